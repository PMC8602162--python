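"""Reduced whole-body PBPK model of rosuvastatin.

Topology
--------
Oral drug enters the first gut-lumen segment and transits segment-by-segment
towards a feces sink.  Absorption into the enterocyte is mediated by apical
OATP2B1 (plus a small passive component); BCRP and Pgp efflux enterocyte drug
back into the lumen.  Drug leaves the enterocyte basolaterally into portal
blood (the slow, rate-limiting passive step), which mixes with hepatic
arterial blood at the liver inlet.  OATP1B1/1B3 takes drug up into the
hepatocyte, where CYP2C9 metabolises a small fraction and canalicular BCRP
secretes the rest into bile; bile drains via the gallbladder back into the
duodenum (enterohepatic recirculation).  In the kidney, basolateral OAT3
uptake followed by apical Pgp secretion plus passive glomerular filtration of
unbound drug (GFR · fu · C) produce urinary excretion.  A lumped peripheral
compartment exchanges with central plasma flow-limited with a single
partition coefficient.

The gut lumen is represented twice — a *dosed* pool and a *recirculated* pool
with identical kinetics.  Bile and gut-wall efflux enter the recirculated
pool, so the fraction of the administered dose absorbed from the lumen
(excluding recycled drug) is available exactly from the dosed-pool feces sink.

Units: amounts µmol, concentrations µmol/L, time h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .compound import ActiveProcess, CompoundParams, validate_processes
from .dosing import DosingProtocol
from .physiology import Physiology
from .units import l_per_h_to_ml_per_min, mg_to_umol, umol_per_l_to_ng_per_ml


class SimulationError(RuntimeError):
    """Raised when the integrator fails or produces an unphysical state."""


# --------------------------------------------------------------------------
# Elementary kinetics
# --------------------------------------------------------------------------

def apparent_km(km: float, inhibitor_conc: float, ki: float) -> float:
    """Apparent Michaelis constant under competitive inhibition.

    Km,app = Km · (1 + I/Ki): a competitive inhibitor raises the apparent
    affinity constant without touching Vmax.
    """
    if km <= 0:
        raise ValueError("km must be positive")
    if ki <= 0:
        raise ValueError("ki must be positive")
    if inhibitor_conc < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    return km * (1.0 + inhibitor_conc / ki)


def michaelis_menten_rate(conc_unbound: float, km_apparent: float, vmax_scaled: float) -> float:
    """Saturable rate v = Vmax · C / (Km + C), bounded above by Vmax."""
    if conc_unbound < 0:
        raise ValueError("concentration must be non-negative")
    if km_apparent <= 0:
        raise ValueError("km_apparent must be positive")
    if vmax_scaled < 0:
        raise ValueError("vmax_scaled must be non-negative")
    return vmax_scaled * conc_unbound / (km_apparent + conc_unbound)


# --------------------------------------------------------------------------
# Model container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PBPKModel:
    """Assembled physiology + compound + active processes.

    ``inhibitor_context`` optionally maps a process key (``name`` or
    ``name@organ_site``) to a callable ``t -> multiplier``; the process Km is
    multiplied by it at integration time (``1 + I(t)/Ki`` for competitive
    inhibition).
    """

    physiology: Physiology
    compound: CompoundParams
    processes: tuple
    inhibitor_context: dict | None = None

    def __post_init__(self) -> None:
        validate_processes(self.processes)
        n_seg = self.physiology.n_lumen_segments
        if len(self.compound.intestinal_permeability_l_per_h) != n_seg:
            raise ValueError("one intestinal permeability per lumen segment required")

    def process(self, name: str, organ_site: str | None = None) -> ActiveProcess:
        for p in self.processes:
            if p.name == name and (organ_site is None or p.organ_site == organ_site):
                return p
        raise KeyError(f"no process {name!r} at site {organ_site!r}")

    def with_inhibition(self, context: dict) -> "PBPKModel":
        return replace(self, inhibitor_context=context)

    def km_multiplier(self, proc: ActiveProcess, t: float) -> float:
        ctx = self.inhibitor_context
        if not ctx:
            return 1.0
        fn = ctx.get(proc.key) or ctx.get(proc.name)
        return 1.0 if fn is None else fn(t)


# --------------------------------------------------------------------------
# State layout
# --------------------------------------------------------------------------

def state_labels(n_seg: int):
    labels = [f"lumen_{i + 1}" for i in range(n_seg)]
    labels += [f"lumen_recirc_{i + 1}" for i in range(n_seg)]
    labels += [
        "enterocyte",
        "portal_vein",
        "liver",
        "gallbladder_bile",
        "kidney",
        "plasma_central",
        "peripheral",
        "urine",
        "feces_dosed",
        "feces_recirc",
        "metabolized",
        "bile_secreted_cum",  # pure accumulator, excluded from the balance
    ]
    return labels


def _indices(n_seg: int):
    i = {}
    i["L"] = list(range(n_seg))
    i["RL"] = list(range(n_seg, 2 * n_seg))
    base = 2 * n_seg
    for j, name in enumerate(
        ["ENT", "POR", "LIV", "GB", "KID", "PLA", "PER", "URN", "FEC_D", "FEC_R", "MET", "BILE"]
    ):
        i[name] = base + j
    i["n"] = base + 12
    return i


# --------------------------------------------------------------------------
# Right-hand side
# --------------------------------------------------------------------------

def pbpk_rhs(t: float, y: np.ndarray, model: PBPKModel, infusion_rate: float = 0.0) -> np.ndarray:
    """Mass-conserving derivative of the compartment amounts (µmol/h).

    The sum of all derivatives over compartments plus sinks is zero (the bile
    accumulator is book-keeping only); an IV infusion adds ``infusion_rate``
    to central plasma.
    """
    p = model.physiology
    c = model.compound
    n_seg = p.n_lumen_segments
    ix = _indices(n_seg)
    dy = np.zeros_like(y)

    fu = c.fraction_unbound_plasma
    v = p.organ_volumes_l
    c_ent = y[ix["ENT"]] / v["enterocyte"]
    c_por = y[ix["POR"]] / v["portal_vein"]
    c_liv = y[ix["LIV"]] / v["liver"]
    c_kid = y[ix["KID"]] / v["kidney"]
    c_pla = y[ix["PLA"]] / v["plasma_central"]
    c_per = y[ix["PER"]] / v["peripheral"]

    def rate(proc_name, site, conc):
        proc = model.process(proc_name, site)
        km = proc.km_umol_per_l * model.km_multiplier(proc, t)
        if conc <= 0.0:
            return 0.0
        return proc.vmax_scaled_umol_per_h * conc / (km + conc)

    # ---- gut lumen: transit + apical uptake / passive absorption ----------
    kt = p.intestinal_transit_rates_per_h
    vlum = p.lumen_volumes_l
    uptake_total = 0.0
    for s in range(n_seg):
        iL, iRL = ix["L"][s], ix["RL"][s]
        c_tot = (y[iL] + y[iRL]) / vlum[s]
        v_2b1 = rate("OATP2B1", "gut_apical", c_tot)
        cl_pass = c.intestinal_permeability_l_per_h[s]
        # split the (shared-carrier) uptake pro rata between the two pools
        pool_tot = y[iL] + y[iRL]
        w_dosed = y[iL] / pool_tot if pool_tot > 0 else 0.0
        for (idx, w) in ((iL, w_dosed), (iRL, 1.0 - w_dosed)):
            flux = w * v_2b1 + cl_pass * y[idx] / vlum[s]
            dy[idx] -= flux
            uptake_total += flux
        # segment-to-segment transit; last segment drains to feces
        for (idx, sink) in ((iL, ix["FEC_D"]), (iRL, ix["FEC_R"])):
            out = kt[s] * y[idx]
            dy[idx] -= out
            if s + 1 < n_seg:
                dy[idx + 1] += out
            else:
                dy[sink] += out
    dy[ix["ENT"]] += uptake_total

    # ---- enterocyte: basolateral exit + apical efflux back to lumen -------
    baso = c.enterocyte_basolateral_clearance_l_per_h * c_ent
    efflux_gut = rate("BCRP", "gut_apical", c_ent) + rate("Pgp", "gut_apical", c_ent)
    dy[ix["ENT"]] -= baso + efflux_gut
    dy[ix["POR"]] += baso
    dy[ix["RL"][0]] += efflux_gut  # effluxed drug re-enters the upper lumen

    # ---- portal vein / liver inlet ----------------------------------------
    q_pv = p.portal_plasma_flow
    q_ha = p.arterial_plasma_flow
    q_h = q_pv + q_ha
    dy[ix["POR"]] += q_pv * (c_pla - c_por)
    dy[ix["PLA"]] += q_pv * (c_por - c_pla)

    # hepatic uptake acts on the unbound mixed liver-inlet concentration and
    # is debited from portal and arterial contributions pro rata
    inlet_por = q_pv * c_por
    inlet_art = q_ha * c_pla
    c_inlet = (inlet_por + inlet_art) / q_h
    v_oatp = rate("OATP1B1_1B3", "liver_basolateral", fu * c_inlet)
    w_por = inlet_por / (inlet_por + inlet_art) if (inlet_por + inlet_art) > 0 else 0.0
    dy[ix["POR"]] -= w_por * v_oatp
    dy[ix["PLA"]] -= (1.0 - w_por) * v_oatp
    dy[ix["LIV"]] += v_oatp

    # ---- hepatocyte: backflux, metabolism, biliary efflux ------------------
    back_liv = c.liver_backflux_clearance_l_per_h * c_liv
    v_met = rate("CYP2C9", "liver_intracellular", c_liv)
    v_bile = rate("BCRP", "liver_canalicular", c_liv)
    dy[ix["LIV"]] -= back_liv + v_met + v_bile
    dy[ix["PLA"]] += back_liv
    dy[ix["MET"]] += v_met
    dy[ix["GB"]] += v_bile
    dy[ix["BILE"]] += v_bile

    # ---- gallbladder: continuous drainage into the duodenum ----------------
    k_gb = p.bile_flow_l_per_h / v["gallbladder_bile"]
    bile_out = k_gb * y[ix["GB"]]
    dy[ix["GB"]] -= bile_out
    dy[ix["RL"][0]] += bile_out

    # ---- kidney: OAT3 uptake, Pgp secretion, filtration --------------------
    v_oat3 = rate("OAT3", "kidney_basolateral", fu * c_pla)
    v_pgp = rate("Pgp", "kidney_apical", c_kid)
    back_kid = c.kidney_backflux_clearance_l_per_h * c_kid
    filtration = p.gfr_l_per_h * fu * c_pla
    dy[ix["PLA"]] -= v_oat3 + filtration
    dy[ix["KID"]] += v_oat3 - v_pgp - back_kid
    dy[ix["PLA"]] += back_kid
    dy[ix["URN"]] += v_pgp + filtration

    # ---- peripheral distribution (flow-limited) ----------------------------
    q_per = p.plasma_flow("peripheral")
    flux_per = q_per * (c_pla - c_per / c.peripheral_partition_coefficient)
    dy[ix["PLA"]] -= flux_per
    dy[ix["PER"]] += flux_per

    dy[ix["PLA"]] += infusion_rate
    return dy


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time course of all compartments plus cumulative sinks.

    ``plasma_concentration_umol_per_l`` refers to the central compartment;
    ``administered_umol`` is the cumulative administered amount at each output
    time, so the mass balance ``sum(compartments) + sinks == administered``
    can be checked point-wise.
    """

    times_h: np.ndarray
    amounts_umol: dict
    dose_umol: float
    molecular_weight: float
    central_volume_l: float

    @property
    def plasma_concentration_umol_per_l(self) -> np.ndarray:
        return self.amounts_umol["plasma_central"] / self.central_volume_l

    @property
    def plasma_concentration_ng_per_ml(self) -> np.ndarray:
        return umol_per_l_to_ng_per_ml(
            self.plasma_concentration_umol_per_l, self.molecular_weight
        )

    @property
    def cumulative_urine_umol(self) -> np.ndarray:
        return self.amounts_umol["urine"]

    @property
    def cumulative_feces_umol(self) -> np.ndarray:
        return self.amounts_umol["feces_dosed"] + self.amounts_umol["feces_recirc"]

    @property
    def cumulative_metabolized_umol(self) -> np.ndarray:
        return self.amounts_umol["metabolized"]

    @property
    def cumulative_bile_secreted_umol(self) -> np.ndarray:
        return self.amounts_umol["bile_secreted_cum"]

    @property
    def administered_umol(self) -> np.ndarray:
        return self.amounts_umol["administered"]

    def mass_balance_error(self) -> float:
        """Max relative |balance residual| over output times with drug present."""
        total = np.zeros_like(self.times_h)
        for name, a in self.amounts_umol.items():
            if name in ("bile_secreted_cum", "administered"):
                continue
            total = total + a
        adm = self.administered_umol
        mask = adm > 0
        if not mask.any():
            return 0.0
        return float(np.max(np.abs(total[mask] - adm[mask]) / adm[mask]))

    def fraction_absorbed(self) -> float:
        """Fraction of the oral dose taken up from the lumen (dosed pool only).

        Excludes biliary-recirculated and gut-wall effluxed drug by
        construction; meaningful once the lumen has emptied.
        """
        if self.dose_umol == 0:
            return 0.0
        residual = sum(
            self.amounts_umol[k][-1]
            for k in self.amounts_umol
            if k.startswith("lumen_") and not k.startswith("lumen_recirc")
        )
        return 1.0 - (self.amounts_umol["feces_dosed"][-1] + residual) / self.dose_umol

    def to_tidy_frame(self):
        """Tidy (time_h, compartment, amount_umol) table."""
        import pandas as pd

        rows = []
        for name, a in self.amounts_umol.items():
            if name == "administered":
                continue
            rows.append(
                pd.DataFrame(
                    {"time_h": self.times_h, "compartment": name, "amount_umol": a}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def plasma_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "conc_ng_per_ml": self.plasma_concentration_ng_per_ml,
            }
        )


def simulate(
    model: PBPKModel,
    protocol: DosingProtocol,
    duration_h: float,
    output_grid_h: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the PBPK system over ``duration_h`` with event restarts.

    Doses are applied as state discontinuities (oral boluses into the first
    lumen segment, IV boluses into central plasma); infusions as a constant
    forcing over their window.  The integration restarts at every dose and
    infusion boundary so the discontinuities never cross a solver step.
    """
    p = model.physiology
    n_seg = p.n_lumen_segments
    ix = _indices(n_seg)
    mw = model.compound.molecular_weight_g_per_mol

    admins = protocol.administrations()
    if admins and duration_h <= admins[-1][0]:
        raise SimulationError("duration must exceed the last dosing event")
    if output_grid_h is None:
        output_grid_h = np.linspace(0.0, duration_h, 481)
    grid = np.asarray(output_grid_h, dtype=float)
    if grid[0] > 0.0:
        grid = np.concatenate([[0.0], grid])

    # breakpoints: dose starts and infusion ends
    breaks = {0.0, duration_h}
    for t0, _, dur in admins:
        breaks.add(t0)
        if dur > 0:
            breaks.add(min(t0 + dur, duration_h))
    breaks = sorted(b for b in breaks if 0.0 <= b <= duration_h)

    y = np.zeros(ix["n"])
    out_t, out_y, out_adm = [], [], []
    administered = 0.0

    def infusion_rate_at(tmid):
        rate = 0.0
        for t0, dose_mg, dur in admins:
            if dur > 0 and t0 <= tmid < t0 + dur:
                rate += mg_to_umol(dose_mg, mw) / dur
        return rate

    for a, b in zip(breaks[:-1], breaks[1:]):
        # apply bolus doses scheduled at the segment start
        for t0, dose_mg, dur in admins:
            if abs(t0 - a) < 1e-12 and dur == 0.0:
                amt = mg_to_umol(dose_mg, mw)
                if protocol.route == "oral":
                    y[ix["L"][0]] += amt
                else:
                    y[ix["PLA"]] += amt
                administered += amt
        rate = infusion_rate_at(0.5 * (a + b))
        t_eval = grid[(grid >= a) & (grid <= b)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        sol = solve_ivp(
            pbpk_rhs,
            (a, b),
            y,
            args=(model, rate),
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
            max_step=np.inf,
        )
        if not sol.success:
            raise SimulationError(f"integrator failed on [{a}, {b}]: {sol.message}")
        # infused amount accrues linearly within the window
        seg_adm = administered + rate * (sol.t - a)
        for k, tk in enumerate(sol.t):
            if tk == a and out_t and out_t[-1] == a:
                continue  # avoid duplicating the restart point
            out_t.append(tk)
            out_y.append(sol.y[:, k])
            out_adm.append(seg_adm[k])
        administered += rate * (b - a)
        y = sol.y[:, -1].copy()

    times = np.array(out_t)
    Y = np.array(out_y).T
    if Y.min() < -max(atol * 1e3, 1e-6 * max(administered, 1.0)):
        raise SimulationError(f"negative state beyond tolerance: {Y.min():g}")
    Y = np.clip(Y, 0.0, None)

    labels = state_labels(n_seg)
    amounts = {lab: Y[i] for i, lab in enumerate(labels)}
    amounts["administered"] = np.array(out_adm)
    keep = np.isin(times, grid)
    amounts = {k: a[keep] for k, a in amounts.items()}
    dose_umol = mg_to_umol(protocol.total_dose_mg, mw)
    return SimulationResult(
        times_h=times[keep],
        amounts_umol=amounts,
        dose_umol=dose_umol,
        molecular_weight=mw,
        central_volume_l=p.organ_volumes_l["plasma_central"],
    )
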