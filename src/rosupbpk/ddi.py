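"""Competitive-inhibition DDI engine.

A perpetrator drug is described by closed-form 1–2 compartment PK (or an
externally supplied concentration table).  Its unbound concentration raises
the apparent Km of each targeted rosuvastatin process competitively,
Km·(1 + I(t)/Ki), during a second ("treated") simulation of the victim;
exposure changes are summarised as DDI AUC_last and Cmax ratios and judged
against the ratio-dependent prediction success envelope of Guest et al.,
which keeps the classical two-fold criterion for strong interactions but
tightens continuously to the 0.8–1.25 bioequivalence band near unity.

Hepatic uptake inhibition is driven by the unbound liver-inlet (portal +
arterial mix) perpetrator concentration; renal and intestinal processes use
unbound systemic plasma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosing import DosingProtocol, oral_single, oral_split
from .metrics import ddi_ratios as _ddi_ratios
from .model import PBPKModel, SimulationResult, simulate
from .poppk import _conc_1cpt_oral_unit, _conc_2cpt_iv_bolus_unit, _conc_2cpt_oral_unit
from .units import mg_to_umol


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PerpetratorModel:
    """Closed-form perpetrator PK (1 cpt if v2/q omitted).

    ``metabolite_fraction`` links a circulating metabolite whose molar
    concentration is that fraction of the parent's (gemfibrozil →
    gemfibrozil 1-O-β-glucuronide); the metabolite carries its own Ki values
    through separate :class:`InhibitionSpec` entries.
    """

    name: str
    molecular_weight_g_per_mol: float
    cl_l_per_h: float
    v1_l: float
    ka_per_h: float = 1.0
    f_bio: float = 1.0
    fu: float = 1.0
    v2_l: float | None = None
    q_l_per_h: float | None = None
    metabolite_fraction: float = 0.0
    metabolite_name: str | None = None

    def __post_init__(self) -> None:
        if self.cl_l_per_h <= 0 or self.v1_l <= 0:
            raise ValueError("CL and V must be positive")
        if not 0 < self.f_bio <= 1:
            raise ValueError("F must lie in (0, 1]")
        if not 0 < self.fu <= 1:
            raise ValueError("fu must lie in (0, 1]")
        if self.metabolite_fraction < 0:
            raise ValueError("metabolite_fraction must be non-negative")


@dataclass(frozen=True)
class InhibitionSpec:
    """perpetrator (or metabolite) -> victim process, with in vitro Ki."""

    perpetrator: str
    target_process: str
    ki_umol_per_l: float

    def __post_init__(self) -> None:
        if self.ki_umol_per_l <= 0:
            raise ValueError("ki must be positive")


@dataclass
class DDIResult:
    auc_last_ratio: float
    cmax_ratio: float
    guest_lower: float
    guest_upper: float
    control: SimulationResult
    treated: SimulationResult

    def within_guest(self, observed_auc_ratio: float) -> bool:
        """Is the predicted AUC ratio inside the envelope around an observed one?"""
        lo, hi = guest_limits(observed_auc_ratio)
        return lo <= self.auc_last_ratio <= hi


# --------------------------------------------------------------------------
# Perpetrator concentrations
# --------------------------------------------------------------------------

def perpetrator_concentration(
    model: PerpetratorModel,
    regimen: DosingProtocol,
    t,
    unbound: bool = False,
) -> np.ndarray:
    """Total (or unbound) perpetrator plasma concentration in µmol/L.

    Closed-form superposition over all administrations; zero before the first
    dose.  Infusion regimens are approximated as boluses at the infusion
    midpoint (perpetrator fidelity is deliberately coarse — the inhibition
    mechanism is the modelled content).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    for t0, dose_mg, dur in regimen.administrations():
        t_eff = t0 + 0.5 * dur
        dose_umol = mg_to_umol(dose_mg, model.molecular_weight_g_per_mol)
        tt = t - t_eff
        if regimen.route == "oral":
            dose_eff = dose_umol * model.f_bio
            if model.v2_l and model.q_l_per_h:
                unit = _conc_2cpt_oral_unit(
                    tt, model.cl_l_per_h, model.v1_l, model.v2_l, model.q_l_per_h,
                    model.ka_per_h,
                )
            else:
                unit = _conc_1cpt_oral_unit(tt, model.cl_l_per_h, model.v1_l, model.ka_per_h)
        else:
            dose_eff = dose_umol
            if model.v2_l and model.q_l_per_h:
                unit = _conc_2cpt_iv_bolus_unit(
                    tt, model.cl_l_per_h, model.v1_l, model.v2_l, model.q_l_per_h
                )
            else:
                ke = model.cl_l_per_h / model.v1_l
                unit = np.where(tt >= 0, np.exp(-ke * np.maximum(tt, 0.0)) / model.v1_l, 0.0)
        out = out + dose_eff * unit
    if unbound:
        out = out * model.fu
    return out


def liver_inlet_concentration(
    model: PerpetratorModel,
    regimen: DosingProtocol,
    t,
    portal_plasma_flow_l_per_h: float,
    unbound: bool = True,
) -> np.ndarray:
    """Unbound perpetrator concentration at the liver inlet.

    Systemic plasma plus the first-pass absorption term
    ka·A_gut(t)/Q_portal for oral regimens (the standard liver-inlet
    convention for uptake-inhibition driving concentrations).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    c = perpetrator_concentration(model, regimen, t, unbound=False)
    if regimen.route == "oral":
        a_gut = np.zeros_like(t)
        for t0, dose_mg, dur in regimen.administrations():
            tt = t - (t0 + 0.5 * dur)
            dose_umol = mg_to_umol(dose_mg, model.molecular_weight_g_per_mol) * model.f_bio
            a_gut += np.where(tt >= 0, dose_umol * np.exp(-model.ka_per_h * np.maximum(tt, 0.0)), 0.0)
        c = c + model.ka_per_h * a_gut / portal_plasma_flow_l_per_h
    return c * (model.fu if unbound else 1.0)


# --------------------------------------------------------------------------
# Guest et al. acceptance envelope
# --------------------------------------------------------------------------

def guest_limits(observed_ratio: float):
    """Ratio-dependent DDI prediction success limits.

    For R ≥ 1: L(R) = (1.25 + 2(R − 1))/R and the limits are (R/L, R·L);
    L(1) = 1.25 reproduces the bioequivalence band and L → 2 as R → ∞.
    Ratios below one are handled symmetrically on the reciprocal.
    """
    r = float(observed_ratio)
    if r <= 0:
        raise ValueError("observed ratio must be positive")
    if r < 1.0:
        lo, hi = guest_limits(1.0 / r)
        return 1.0 / hi, 1.0 / lo
    limit = (1.25 + 2.0 * (r - 1.0)) / r
    return r / limit, r * limit


def within_guest(predicted_ratio: float, observed_ratio: float) -> bool:
    lo, hi = guest_limits(observed_ratio)
    return lo <= predicted_ratio <= hi


# --------------------------------------------------------------------------
# Absorption-protocol switching
# --------------------------------------------------------------------------

def absorption_variant(protocol: DosingProtocol, perpetrator: str | None) -> DosingProtocol:
    """Oral absorption protocol appropriate for a DDI arm.

    Rifampicin and probenecid co-treatment abolish the delayed second
    release (single release at t = 0); gemfibrozil and monotherapy keep the
    split protocol.
    """
    if protocol.route != "oral":
        raise ValueError("absorption variants apply to oral protocols")
    if perpetrator in ("rifampicin", "probenecid"):
        return oral_single(
            protocol.total_dose_mg, protocol.repeat_interval_h, protocol.n_repeats
        )
    return oral_split(
        protocol.total_dose_mg, protocol.repeat_interval_h, protocol.n_repeats
    )


# --------------------------------------------------------------------------
# Paired co-simulation
# --------------------------------------------------------------------------

#: Process names whose driving perpetrator concentration is the liver inlet.
_HEPATIC_PROCESSES = {"OATP1B1_1B3"}


def build_inhibitor_context(
    victim: PBPKModel,
    perpetrators: dict,
    specs,
    perp_regimens: dict,
):
    """Map victim process names to time-varying Km multipliers 1 + Σ I(t)/Ki.

    ``perpetrators`` maps perpetrator/metabolite names to
    :class:`PerpetratorModel` entries (a metabolite is resolved through its
    parent's ``metabolite_fraction``); ``perp_regimens`` maps parent names to
    their dosing regimens.
    """
    q_portal = victim.physiology.portal_plasma_flow
    terms: dict[str, list] = {}
    for spec in specs:
        name = spec.perpetrator
        parent = None
        scale = 1.0
        if name in perp_regimens:
            parent = perpetrators[name]
        else:
            for p in perpetrators.values():
                if p.metabolite_name == name:
                    parent, scale = p, p.metabolite_fraction
                    break
            if parent is None:
                raise ConfigurationError(f"no PK model or table for perpetrator {name!r}")
        regimen = perp_regimens[parent.name]
        hepatic = spec.target_process in _HEPATIC_PROCESSES
        terms.setdefault(spec.target_process, []).append(
            (parent, regimen, scale, spec.ki_umol_per_l, hepatic)
        )

    context = {}
    for process, entries in terms.items():
        def mult(t, entries=entries):
            total = 0.0
            for parent, regimen, scale, ki, hepatic in entries:
                if hepatic:
                    conc = liver_inlet_concentration(
                        parent, regimen, t, q_portal, unbound=True
                    )
                else:
                    conc = perpetrator_concentration(parent, regimen, t, unbound=True)
                total += scale * float(np.atleast_1d(conc)[0]) / ki
            return 1.0 + total
        context[process] = mult
    return context


def simulate_ddi(
    victim: PBPKModel,
    perpetrator: PerpetratorModel,
    specs,
    victim_regimen: DosingProtocol,
    perp_regimen: DosingProtocol,
    duration_h: float,
    output_grid_h=None,
    extra_perpetrators: dict | None = None,
    **sim_kwargs,
) -> DDIResult:
    """Run victim-alone and victim-with-inhibition simulations and compare.

    Both arms use the same victim regimen and the same output window from
    victim dose time to ``duration_h``, so the AUC_last ratio is evaluated on
    a common window.  A parent's linked metabolite contributes its own
    inhibition terms through specs naming the metabolite.
    """
    for spec in specs:
        try:
            victim.process(spec.target_process)
        except KeyError:
            raise ConfigurationError(
                f"inhibition target {spec.target_process!r} not in victim model"
            )
    perpetrators = {perpetrator.name: perpetrator}
    if extra_perpetrators:
        perpetrators.update(extra_perpetrators)
    regimens = {name: perp_regimen for name in perpetrators}

    control = simulate(victim, victim_regimen, duration_h, output_grid_h, **sim_kwargs)
    if specs:
        context = build_inhibitor_context(victim, perpetrators, specs, regimens)
        treated_model = victim.with_inhibition(context)
        treated = simulate(
            treated_model, victim_regimen, duration_h, output_grid_h, **sim_kwargs
        )
    else:
        treated = control
    auc_ratio, cmax_ratio = _ddi_ratios(
        (control.times_h, control.plasma_concentration_ng_per_ml),
        (treated.times_h, treated.plasma_concentration_ng_per_ml),
    )
    lo, hi = guest_limits(auc_ratio)
    return DDIResult(auc_ratio, cmax_ratio, lo, hi, control, treated)
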