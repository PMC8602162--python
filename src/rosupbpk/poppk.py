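"""Two-compartment split-dose population PK model of rosuvastatin.

The oral absorption phase is represented as two sub-doses absorbed with the
same first-order rate constant: a fraction ``1 − f_second`` released
immediately and ``f_second`` released after a lag ``lag_second`` (population
medians 63.4% / 36.6% with a 2.3 h lag).  Disposition is a linear
two-compartment model with first-order elimination from the central
compartment.  Mixed-effects estimation is replaced by a two-stage procedure:
per-subject multi-start least squares on log concentrations, then
component-wise population medians and log-scale dispersions.

``SplitDosePopPK`` / ``PopPKResults`` follow the model/results split familiar
from statsmodels: the model is built from a subject's observations and
``fit()`` returns a results object carrying estimates and diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopPKParams:
    """Fixed-effect parameters (apparent, i.e. scaled by bioavailability).

    ``iiv_sd`` maps {"f_second", "f_bio", "cl"} to the SD of the log-scale
    (exponential) interindividual random effect; ``sigma_prop`` is the
    proportional residual SD.
    """

    cl_l_per_h: float = 141.0
    v1_l: float = 225.0
    v2_l: float = 1880.0
    q_l_per_h: float = 140.0
    ka_per_h: float = 0.45
    f_second: float = 0.366
    lag_second_h: float = 2.3
    f_bio: float = 1.0
    iiv_sd: dict = field(
        default_factory=lambda: {"f_second": 0.2, "f_bio": 0.3, "cl": 0.3}
    )
    sigma_prop: float = 0.2

    def __post_init__(self) -> None:
        for name in ("cl_l_per_h", "v1_l", "v2_l", "q_l_per_h", "ka_per_h", "f_bio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.f_second < 1:
            raise ValueError("f_second must lie in [0, 1)")
        if self.lag_second_h < 0:
            raise ValueError("lag_second must be non-negative")


#: Final split-dose parameterization used to generate virtual cohorts.
FINAL_POPPK = PopPKParams()


@dataclass(frozen=True)
class CovariateFactors:
    """Multiplicative DDI covariate effects on bioavailability and clearance,
    plus the absorption mode the arm requires."""

    ddi_label: str = "none"
    factor_on_f_bio: float = 1.0
    factor_on_cl: float = 1.0
    absorption_mode: str = "split"

    def __post_init__(self) -> None:
        if self.factor_on_f_bio <= 0 or self.factor_on_cl <= 0:
            raise ValueError("covariate factors must be positive")
        if self.absorption_mode not in ("split", "single"):
            raise ValueError("absorption_mode must be 'split' or 'single'")


#: Default DDI covariate sets (exposure multipliers are package defaults, the
#: absorption modes follow the population analysis of the DDI arms).
DDI_COVARIATES = {
    "none": CovariateFactors(),
    "rifampicin": CovariateFactors("rifampicin", 3.0, 0.8, "single"),
    "gemfibrozil": CovariateFactors("gemfibrozil", 1.9, 1.0, "split"),
    "probenecid": CovariateFactors("probenecid", 1.6, 0.9, "single"),
}


# --------------------------------------------------------------------------
# Analytic concentration
# --------------------------------------------------------------------------

def _macro_constants(cl, v1, v2, q):
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return k21, alpha, beta


def _conc_2cpt_oral_unit(t, cl, v1, v2, q, ka):
    """Unit-dose (1 mg) oral two-compartment concentration in mg/L."""
    t = np.asarray(t, dtype=float)
    k21, alpha, beta = _macro_constants(cl, v1, v2, q)
    # guard against coincident rate constants (measure-zero; nudge ka)
    for lam in (alpha, beta):
        if abs(ka - lam) < 1e-10 * max(ka, lam):
            ka = ka * (1.0 + 1e-8)
    A = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    B = (k21 - beta) / ((ka - beta) * (alpha - beta))
    C = (k21 - ka) / ((alpha - ka) * (beta - ka))
    pos = t >= 0
    out = np.zeros_like(t)
    tp = t[pos]
    out[pos] = (ka / v1) * (
        A * np.exp(-alpha * tp) + B * np.exp(-beta * tp) + C * np.exp(-ka * tp)
    )
    return out


def _conc_2cpt_iv_bolus_unit(t, cl, v1, v2, q):
    """Unit-dose (1 mg) IV-bolus two-compartment concentration in mg/L."""
    t = np.asarray(t, dtype=float)
    k21, alpha, beta = _macro_constants(cl, v1, v2, q)
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)
    pos = t >= 0
    out = np.zeros_like(t)
    tp = t[pos]
    out[pos] = (1.0 / v1) * (A * np.exp(-alpha * tp) + B * np.exp(-beta * tp))
    return out


def _conc_1cpt_oral_unit(t, cl, v, ka):
    t = np.asarray(t, dtype=float)
    ke = cl / v
    if abs(ka - ke) < 1e-10 * max(ka, ke):
        ka = ka * (1.0 + 1e-8)
    pos = t >= 0
    out = np.zeros_like(t)
    tp = t[pos]
    out[pos] = (ka / (v * (ka - ke))) * (np.exp(-ke * tp) - np.exp(-ka * tp))
    return out


def poppk_concentration(
    t,
    params: PopPKParams,
    dose_mg: float,
    covariates: CovariateFactors | None = None,
) -> np.ndarray:
    """Plasma concentration (ng/mL) at time(s) ``t`` after a single oral dose.

    In split mode the profile is the superposition of the immediate sub-dose
    ``dose·(1 − f_second)`` and the lagged sub-dose ``dose·f_second`` shifted
    by ``lag_second``; in single mode one term carries the whole dose with no
    lag.
    """
    cov = covariates or CovariateFactors()
    cl = params.cl_l_per_h * cov.factor_on_cl
    f = params.f_bio * cov.factor_on_f_bio
    t = np.atleast_1d(np.asarray(t, dtype=float))

    def term(dose, shift):
        return dose * f * _conc_2cpt_oral_unit(
            t - shift, cl, params.v1_l, params.v2_l, params.q_l_per_h, params.ka_per_h
        )

    if cov.absorption_mode == "single" or params.f_second == 0.0:
        c_mg_per_l = term(dose_mg, 0.0)
    else:
        c_mg_per_l = term(dose_mg * (1.0 - params.f_second), 0.0) + term(
            dose_mg * params.f_second, params.lag_second_h
        )
    return c_mg_per_l * 1000.0  # mg/L -> ng/mL


# --------------------------------------------------------------------------
# Per-subject fitting (two-stage stage 1)
# --------------------------------------------------------------------------

_FIT_DEFAULT_FREE = ("cl_l_per_h", "v1_l", "ka_per_h", "f_second", "lag_second_h")
_LOG_PARAMS = ("cl_l_per_h", "v1_l", "v2_l", "q_l_per_h", "ka_per_h")


class FitError(RuntimeError):
    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


def _pack(params: PopPKParams, free):
    x = []
    for name in free:
        v = getattr(params, name)
        if name in _LOG_PARAMS:
            x.append(math.log(v))
        elif name == "f_second":
            v = min(max(v, 1e-6), 1 - 1e-6)
            x.append(math.log(v / (1 - v)))
        elif name == "lag_second_h":
            x.append(math.log(max(v, 1e-6)))
        else:
            x.append(v)
    return np.array(x)


def _unpack(x, params: PopPKParams, free) -> PopPKParams:
    updates = {}
    for name, xi in zip(free, x):
        if name in _LOG_PARAMS or name == "lag_second_h":
            updates[name] = math.exp(xi)
        elif name == "f_second":
            updates[name] = 1.0 / (1.0 + math.exp(-xi))
        else:
            updates[name] = xi
    return replace(params, **updates)


@dataclass
class PopPKResults:
    """Per-subject estimates with residual diagnostics (results object)."""

    params: PopPKParams
    sse: float
    converged: bool
    n_obs: int
    n_free: int
    residuals_log: np.ndarray
    mode: str = "split"

    @property
    def aicc(self) -> float:
        """Small-sample information criterion on the log-residual SSE."""
        n, k = self.n_obs, self.n_free
        aic = n * math.log(self.sse / n) + 2 * k
        denom = n - k - 1
        return aic + (2 * k * (k + 1) / denom if denom > 0 else math.inf)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Split-dose PopPK fit" if self.mode == "split" else "Single-absorption PopPK fit",
            f"  n_obs={self.n_obs}  free={self.n_free}  SSE(log)={self.sse:.5g}  "
            f"converged={self.converged}",
            f"  CL/F = {p.cl_l_per_h:8.3f} L/h    V1/F = {p.v1_l:8.2f} L",
            f"  V2/F = {p.v2_l:8.1f} L      Q/F  = {p.q_l_per_h:8.2f} L/h",
            f"  ka   = {p.ka_per_h:8.4f} 1/h",
        ]
        if self.mode == "split":
            lines.append(
                f"  f_second = {p.f_second:6.4f}    lag_second = {p.lag_second_h:6.3f} h"
            )
        return "\n".join(lines)


class SplitDosePopPK:
    """Model object for one subject's oral concentration–time data.

    With ``tie_dispersion_scale`` (default) the fixed peripheral constants
    V2/F and Q/F are rescaled by the fitted V1/F relative to its initial
    value, so a subject-level bioavailability shift — which scales *all*
    apparent volumes and clearances equally — stays inside the fitted model
    family even though only V1 and CL are free.
    """

    def __init__(self, times_h, conc_ng_per_ml, dose_mg, mode: str = "split",
                 tie_dispersion_scale: bool = True):
        t = np.asarray(times_h, dtype=float)
        c = np.asarray(conc_ng_per_ml, dtype=float)
        keep = c > 0
        self.times_h = t[keep]
        self.conc = c[keep]
        self.dose_mg = float(dose_mg)
        if mode not in ("split", "single"):
            raise ValueError("mode must be 'split' or 'single'")
        self.mode = mode
        self.tie_dispersion_scale = tie_dispersion_scale

    @classmethod
    def from_dataframe(cls, df, dose_mg=None, mode="split"):
        dose = float(df["dose_mg"].iloc[0]) if dose_mg is None else dose_mg
        return cls(df["time_h"].to_numpy(), df["conc_ng_per_ml"].to_numpy(), dose, mode)

    def predict(self, params: PopPKParams, t=None):
        cov = CovariateFactors(absorption_mode=self.mode)
        return poppk_concentration(
            self.times_h if t is None else t, params, self.dose_mg, cov
        )

    def fit(
        self,
        init: PopPKParams | None = None,
        fixed: frozenset | set = frozenset(),
        n_starts: int = 10,
        seed: int = 0,
        spread: float = 0.5,
    ) -> PopPKResults:
        """Multi-start Levenberg–Marquardt least squares on log concentrations.

        Starts are drawn log-uniformly around ``init`` (span e^±spread); all
        parameters are transformed to an unconstrained scale, so the plain LM
        algorithm applies.  Raises :class:`FitError` carrying the best attempt
        when no start converges.
        """
        init = init or FINAL_POPPK
        free = [p for p in _FIT_DEFAULT_FREE if p not in fixed]
        if self.mode == "single":
            free = [p for p in free if p not in ("f_second", "lag_second_h")]
        if not free:
            res_log = np.log(self.predict(init)) - np.log(self.conc)
            return PopPKResults(
                init, float(res_log @ res_log), True, self.conc.size, 0, res_log, self.mode
            )
        if self.conc.size < len(free):
            raise FitError("fewer informative observations than free parameters")

        tie = (
            self.tie_dispersion_scale
            and "v1_l" in free
            and "v2_l" not in free
            and "q_l_per_h" not in free
        )

        def _tie(p):
            if not tie:
                return p
            s = p.v1_l / init.v1_l
            return replace(p, v2_l=init.v2_l * s, q_l_per_h=init.q_l_per_h * s)

        def residuals(x):
            p = _tie(_unpack(x, init, free))
            pred = self.predict(p)
            pred = np.maximum(pred, 1e-12)
            return np.log(pred) - np.log(self.conc)

        rng = np.random.default_rng(seed)
        x0 = _pack(init, free)
        best = None
        for start in range(max(n_starts, 1)):
            xs = x0 if start == 0 else x0 + rng.uniform(-spread, spread, size=x0.size)
            try:
                sol = least_squares(residuals, xs, method="lm", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            sse = float(sol.fun @ sol.fun)
            if best is None or sse < best[0]:
                best = (sse, sol)
        if best is None:
            raise FitError("all starts failed")
        sse, sol = best
        params = _tie(_unpack(sol.x, init, free))
        if self.mode == "single":
            params = replace(params, f_second=0.0, lag_second_h=0.0)
        return PopPKResults(
            params, sse, bool(sol.status > 0), self.conc.size, len(free), sol.fun, self.mode
        )


def fit_individual(
    observations,
    dose_mg: float,
    init: PopPKParams | None = None,
    fixed=frozenset(),
    mode: str = "split",
    n_starts: int = 10,
    seed: int = 0,
) -> PopPKResults:
    """Fit one subject from a list of (time_h, conc_ng_per_ml) pairs."""
    obs = np.asarray(list(observations), dtype=float)
    if obs.size == 0 or not np.any(obs[:, 1] > 0):
        raise FitError("no quantifiable observations")
    model = SplitDosePopPK(obs[:, 0], obs[:, 1], dose_mg, mode=mode)
    return model.fit(init=init, fixed=fixed, n_starts=n_starts, seed=seed)


# --------------------------------------------------------------------------
# Population summary (two-stage stage 2) and structural model selection
# --------------------------------------------------------------------------

@dataclass
class PopulationSummary:
    medians: dict
    log_sd: dict
    n_subjects: int

    def summary(self) -> str:
        lines = [f"Population summary over {self.n_subjects} subjects", "  parameter        median      log-SD"]
        for k in self.medians:
            lines.append(f"  {k:<16s} {self.medians[k]:>9.4g}   {self.log_sd[k]:>7.4f}")
        return "\n".join(lines)


_SUMMARY_FIELDS = (
    "cl_l_per_h", "v1_l", "v2_l", "q_l_per_h", "ka_per_h", "f_second", "lag_second_h",
)


def summarize_population(results) -> PopulationSummary:
    """Component-wise medians and log-scale SDs across per-subject estimates."""
    results = list(results)
    if len(results) < 2:
        raise ValueError("at least two subjects are required")
    medians, log_sd = {}, {}
    for name in _SUMMARY_FIELDS:
        vals = np.array([getattr(r.params, name) for r in results], dtype=float)
        medians[name] = float(np.median(vals))
        pos = vals[vals > 0]
        log_sd[name] = float(np.std(np.log(pos), ddof=1)) if pos.size == vals.size else float("nan")
    return PopulationSummary(medians, log_sd, len(results))


def select_absorption_model(fit_split: PopPKResults, fit_single: PopPKResults) -> str:
    """Choose 'split' or 'single' by the small-sample information criterion.

    The split model spends two extra parameters (f_second, lag_second); ties
    break towards the single model (parsimony).
    """
    if fit_split.aicc < fit_single.aicc:
        return "split"
    return "single"
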