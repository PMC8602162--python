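"""Virtual clinical-study generator.

Replaces the digitised literature datasets with synthetic studies that carry
the statistical structure the analysis assumes: a mean virtual individual
per study, log-normal interindividual variability on selected parameters,
proportional (log-normal) residual error on plasma samples, and censoring
below the lower limit of quantification.  Everything is reproducible from a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationObservation,
    CalibrationStudy,
    TrainingDataset,
    set_param,
)
from .dosing import DosingProtocol, iv_bolus, oral_split
from .model import PBPKModel, simulate
from .physiology import REFERENCE_DEMOGRAPHICS, Demographics
from .poppk import CovariateFactors, PopPKParams, poppk_concentration

#: Default plasma sampling grid (h): 14 points, dense over the absorption
#: phase (0.5-4 h brackets the 2.3 h release lag), out to 96 h.
DEFAULT_SAMPLING_H = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0, 12.0, 24.0, 96.0)
#: Cumulative urine/feces collection grid (h).
DEFAULT_EXCRETA_H = (24.0, 48.0, 96.0, 168.0, 240.0)


@dataclass(frozen=True)
class StudyDesign:
    study_id: str
    regimen: DosingProtocol
    demographics: Demographics = REFERENCE_DEMOGRAPHICS
    n_subjects: int = 1
    sampling_times_h: tuple = DEFAULT_SAMPLING_H
    collect_plasma: bool = True
    collect_urine: bool = False
    collect_feces: bool = False
    ddi_arm: tuple | None = None  # (perpetrator_name, DosingProtocol)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        t = np.asarray(self.sampling_times_h)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")


@dataclass(frozen=True)
class ErrorModel:
    """Between-subject and assay noise.

    ``iiv_cv`` maps a parameter name (PopPK field or PBPK parameter path) to
    a log-normal coefficient of variation; ``residual_prop_sd`` is the SD of
    the additive error on log concentration (proportional error);
    observations below ``lloq_ng_per_ml`` are censored.
    """

    iiv_cv: dict = field(default_factory=dict)
    residual_prop_sd: float = 0.2
    lloq_ng_per_ml: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for cv in self.iiv_cv.values():
            if cv < 0:
                raise ValueError("CVs must be non-negative")
        if self.residual_prop_sd < 0 or self.lloq_ng_per_ml < 0:
            raise ValueError("residual SD and LLOQ must be non-negative")


@dataclass(frozen=True)
class ObservationRecord:
    subject_id: str
    study_id: str
    arm: str
    time_h: float
    value: float
    obs_type: str  # plasma | urine_cumulative | feces_cumulative
    dose_mg: float
    route: str
    censored: bool = False


def records_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.rename(columns={"value": "conc_ng_per_ml"})


def _lognormal_factor(rng, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sd = np.sqrt(np.log(1.0 + cv * cv))
    # median-preserving log-normal perturbation
    return float(np.exp(rng.normal(0.0, sd)))


# --------------------------------------------------------------------------
# PopPK cohort generation
# --------------------------------------------------------------------------

def generate_poppk_cohort(
    params: PopPKParams,
    design: StudyDesign,
    errors: ErrorModel,
    covariates: CovariateFactors | None = None,
):
    """Per-subject observation records from the analytic split-dose model.

    Subjects draw median-preserving log-normal perturbations of the
    parameters named in ``errors.iiv_cv``; each plasma sample is multiplied
    by exp(N(0, residual_prop_sd)) and censored below the LLOQ.
    """
    rng = np.random.default_rng(errors.seed)
    records = []
    dose = design.regimen.total_dose_mg
    for s in range(design.n_subjects):
        updates = {}
        for name, cv in errors.iiv_cv.items():
            base = getattr(params, name, None)
            if base is None:
                continue
            value = base * _lognormal_factor(rng, cv)
            if name == "f_second":
                value = min(value, 0.95)
            updates[name] = value
        subject_params = replace(params, **updates)
        conc = poppk_concentration(
            np.asarray(design.sampling_times_h), subject_params, dose, covariates
        )
        noise = np.exp(rng.normal(0.0, errors.residual_prop_sd, size=conc.size))
        observed = conc * noise
        for t, c in zip(design.sampling_times_h, observed):
            censored = c < errors.lloq_ng_per_ml
            records.append(
                ObservationRecord(
                    f"{design.study_id}-{s + 1:03d}",
                    design.study_id,
                    "control" if design.ddi_arm is None else design.ddi_arm[0],
                    float(t),
                    float(c) if not censored else float("nan"),
                    "plasma",
                    dose,
                    design.regimen.route,
                    censored=censored,
                )
            )
    return records


# --------------------------------------------------------------------------
# PBPK study generation
# --------------------------------------------------------------------------

def generate_study(model: PBPKModel, design: StudyDesign, errors: ErrorModel):
    """Observation records from per-subject perturbed PBPK simulations."""
    rng = np.random.default_rng(errors.seed)
    records = []
    grid = np.unique(
        np.concatenate(
            [
                [0.0],
                np.asarray(design.sampling_times_h, dtype=float),
                np.asarray(DEFAULT_EXCRETA_H, dtype=float)
                if (design.collect_urine or design.collect_feces)
                else [],
            ]
        )
    )
    duration = float(grid[-1]) * 1.0001
    for s in range(design.n_subjects):
        m = model
        for path, cv in errors.iiv_cv.items():
            try:
                from .calibration import get_param

                base = get_param(m, path)
            except (KeyError, AttributeError):
                continue
            m = set_param(m, path, base * _lognormal_factor(rng, cv))
        result = simulate(m, design.regimen, duration, grid, rtol=1e-6, atol=1e-9)
        sid = f"{design.study_id}-{s + 1:03d}"
        arm = "control" if design.ddi_arm is None else design.ddi_arm[0]
        dose = design.regimen.total_dose_mg
        if design.collect_plasma:
            conc = np.interp(
                design.sampling_times_h, result.times_h, result.plasma_concentration_ng_per_ml
            )
            noise = np.exp(rng.normal(0.0, errors.residual_prop_sd, size=conc.size))
            observed = conc * noise
            for t, c in zip(design.sampling_times_h, observed):
                censored = c < errors.lloq_ng_per_ml
                records.append(
                    ObservationRecord(
                        sid, design.study_id, arm, float(t),
                        float(c) if not censored else float("nan"),
                        "plasma", dose, design.regimen.route, censored=censored,
                    )
                )
        for flag, obs_type, series in (
            (design.collect_urine, "urine_cumulative", result.cumulative_urine_umol),
            (design.collect_feces, "feces_cumulative", result.cumulative_feces_umol),
        ):
            if not flag:
                continue
            frac = np.interp(DEFAULT_EXCRETA_H, result.times_h, series) / result.dose_umol
            for t, v in zip(DEFAULT_EXCRETA_H, frac):
                records.append(
                    ObservationRecord(
                        sid, design.study_id, arm, float(t), float(v),
                        obs_type, dose, design.regimen.route,
                    )
                )
    return records


# --------------------------------------------------------------------------
# Packaged fixture suite
# --------------------------------------------------------------------------

def fixture_suite(model: PBPKModel, seed: int = 0):
    """A reduced virtual-study set: training dataset + DDI study designs.

    Mirrors the composition of a rosuvastatin development dataset at desk
    scale: an IV microdose-like arm, oral arms over three dose levels, a
    multiple-dose arm and a urine/feces mass-balance study (training), plus
    rifampicin (IV and oral perpetrator), gemfibrozil and probenecid DDI
    arms.
    """
    designs = {
        "iv-microdose": StudyDesign("iv-microdose", iv_bolus(0.002)),
        "oral-10": StudyDesign("oral-10", oral_split(10.0)),
        "oral-40": StudyDesign("oral-40", oral_split(40.0)),
        "oral-80": StudyDesign("oral-80", oral_split(80.0)),
        "oral-md": StudyDesign(
            "oral-md", oral_split(40.0, repeat_interval_h=24.0, n_repeats=3)
        ),
        "mass-balance": StudyDesign(
            "mass-balance", oral_split(20.0), collect_urine=True, collect_feces=True
        ),
    }
    from .dosing import iv_infusion, oral_single

    ddi_designs = [
        StudyDesign("ddi-rif-iv", oral_single(20.0), ddi_arm=("rifampicin", iv_infusion(600.0, 0.5))),
        StudyDesign("ddi-rif-oral", oral_single(20.0), ddi_arm=("rifampicin", oral_single(600.0))),
        StudyDesign("ddi-gem", oral_split(80.0), ddi_arm=("gemfibrozil", oral_single(600.0, repeat_interval_h=12.0, n_repeats=4))),
        StudyDesign("ddi-prob", oral_single(40.0), ddi_arm=("probenecid", oral_single(500.0))),
    ]

    errors = ErrorModel(residual_prop_sd=0.2, seed=seed)
    training_ids = ("iv-microdose", "oral-40", "mass-balance")
    studies = []
    test_records = {}
    for study_id, design in designs.items():
        recs = generate_study(
            model, design, replace(errors, seed=seed + abs(hash(study_id)) % 10_000)
        )
        if study_id in training_ids:
            obs = tuple(
                CalibrationObservation(r.time_h, r.value, r.obs_type)
                for r in recs
                if not r.censored
            )
            studies.append(CalibrationStudy(study_id, design.regimen, obs))
        else:
            test_records[study_id] = recs
    return TrainingDataset(tuple(studies)), test_records, ddi_designs
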