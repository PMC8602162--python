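"""Non-compartmental analysis and model-evaluation statistics.

Implements the evaluation measures used throughout the pipeline: AUC by
linear trapezoid, sampled Cmax/tmax, terminal half-life by log-linear
regression, mean relative deviation (MRD) of predicted plasma
concentrations, geometric mean fold error (GMFE) of predicted PK parameters,
DDI exposure ratios, and mass-balance-based excretion summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import l_per_h_to_ml_per_min


@dataclass
class NCAResult:
    auc_last_ng_h_per_ml: float
    auc_inf_ng_h_per_ml: float
    cmax_ng_per_ml: float
    tmax_h: float
    t_half_terminal_h: float | None = None
    cl_renal_ml_per_min: float | None = None
    fe_urine: float | None = None
    fe_feces: float | None = None
    f_bioavailability: float | None = None


def auc_last(times_h, conc) -> float:
    """Linear-trapezoid AUC from the first to the last sample."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise ValueError("at least two samples are required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return float(np.trapezoid(c, t))


def auc_log_trapezoid(times_h, conc) -> float:
    """Log-down trapezoid (linear-up/log-down) alternative AUC rule."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise ValueError("at least two samples are required")
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            total += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            total += dt * 0.5 * (c1 + c2)
    return float(total)


def mrd(predicted, observed) -> float:
    """Mean relative deviation 10^sqrt(mean((log10 pred − log10 obs)^2)) ≥ 1."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must be equal-length, non-empty")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("concentrations must be positive for log deviation")
    x = np.sqrt(np.mean((np.log10(p) - np.log10(o)) ** 2))
    return float(10.0 ** x)


def gmfe(pairs) -> float:
    """Geometric mean fold error 10^(mean |log10(pred/obs)|) ≥ 1, symmetric."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one (predicted, observed) pair is required")
    if np.any(arr <= 0):
        raise ValueError("PK parameters must be positive")
    x = np.mean(np.abs(np.log10(arr[:, 0] / arr[:, 1])))
    return float(10.0 ** x)


def cmax_tmax(times_h, conc):
    """Sampled maximum and its time (no interpolation)."""
    c = np.asarray(conc, dtype=float)
    i = int(np.argmax(c))
    return float(c[i]), float(np.asarray(times_h, dtype=float)[i])


def terminal_half_life(times_h, conc, n_tail: int = 4) -> float:
    """ln2 / slope of the least-squares line on ln(conc) over the tail."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    mask = c > 0
    t, c = t[mask], c[mask]
    if n_tail < 3:
        raise ValueError("n_tail must be >= 3")
    if t.size < n_tail:
        raise ValueError("not enough positive tail samples")
    t_tail, c_tail = t[-n_tail:], c[-n_tail:]
    slope, _ = np.polyfit(t_tail, np.log(c_tail), 1)
    if slope >= 0:
        raise ValueError("no terminal decline (non-negative slope)")
    return float(np.log(2.0) / -slope)


def tail_samples_past(times_h, conc, cutoff_h: float = 24.0, n_min: int = 4):
    """Default terminal-phase rule: all samples past the cutoff, or the last
    ``n_min`` samples, whichever set is larger."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    late = t > cutoff_h
    if late.sum() >= n_min:
        return t[late], c[late]
    return t[-n_min:], c[-n_min:]


def ddi_ratios(control, treated):
    """(AUC_last ratio, Cmax ratio) = treated / control.

    Accepts either :class:`NCAResult`-like objects (with
    ``auc_last_ng_h_per_ml`` / ``cmax_ng_per_ml``) or raw ``(times, conc)``
    profile tuples evaluated on matching windows.
    """
    def _extract(x):
        if hasattr(x, "auc_last_ng_h_per_ml"):
            return x.auc_last_ng_h_per_ml, x.cmax_ng_per_ml
        t, c = x
        return auc_last(t, c), cmax_tmax(t, c)[0]

    auc_c, cmax_c = _extract(control)
    auc_t, cmax_t = _extract(treated)
    if auc_c <= 0 or cmax_c <= 0:
        raise ValueError("control AUC and Cmax must be positive")
    return auc_t / auc_c, cmax_t / cmax_c


def nca(times_h, conc_ng_per_ml, extrapolate: bool = True) -> NCAResult:
    """Standard NCA on a plasma profile (ng/mL over h)."""
    aucl = auc_last(times_h, conc_ng_per_ml)
    cmax, tmax = cmax_tmax(times_h, conc_ng_per_ml)
    t_half = None
    auc_inf = aucl
    if extrapolate:
        try:
            tt, cc = tail_samples_past(times_h, conc_ng_per_ml)
            t_half = terminal_half_life(tt, cc, n_tail=len(tt))
            clast = np.asarray(conc_ng_per_ml)[-1]
            auc_inf = aucl + clast * t_half / np.log(2.0)
        except ValueError:
            pass
    return NCAResult(aucl, auc_inf, cmax, tmax, t_half_terminal_h=t_half)


@dataclass
class ExcretionSummary:
    fe_urine: float
    fe_feces: float
    fe_metabolized: float
    cl_renal_ml_per_min: float
    mass_balance_closed: bool


def excretion_summary(result, dose_umol: float | None = None, closure: float = 0.99) -> ExcretionSummary:
    """Fractions excreted and renal clearance from a simulation.

    ``fe`` values are cumulative sink amounts over the administered dose;
    renal clearance is cumulative urine amount divided by the plasma AUC(0–t)
    in µmol·h/L, converted to mL/min.  If less than ``closure`` of the dose
    has reached the sinks by the end of the simulation, the summary is
    flagged as not mass-balance closed (values still returned).
    """
    dose = result.dose_umol if dose_umol is None else dose_umol
    if dose <= 0:
        raise ValueError("dose must be positive")
    urine = float(result.cumulative_urine_umol[-1])
    feces = float(result.cumulative_feces_umol[-1])
    met = float(result.cumulative_metabolized_umol[-1])
    auc_umol_h = auc_last(result.times_h, result.plasma_concentration_umol_per_l)
    cl_renal = l_per_h_to_ml_per_min(urine / auc_umol_h) if auc_umol_h > 0 else 0.0
    closed = (urine + feces + met) >= closure * dose
    return ExcretionSummary(urine / dose, feces / dose, met / dose, cl_renal, closed)


def bioavailability(oral_result, iv_result, oral_dose_mg: float, iv_dose_mg: float) -> float:
    """Dose-normalised oral/IV AUC(0–last) ratio from paired simulations."""
    auc_oral = auc_last(oral_result.times_h, oral_result.plasma_concentration_ng_per_ml)
    auc_iv = auc_last(iv_result.times_h, iv_result.plasma_concentration_ng_per_ml)
    if auc_iv <= 0:
        raise ValueError("IV AUC must be positive")
    return (auc_oral / oral_dose_mg) / (auc_iv / iv_dose_mg)
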