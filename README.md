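# rosupbpk

Reduced whole-body physiologically based pharmacokinetic (PBPK) and
population PK modelling of **rosuvastatin**, with mechanistic simulation of
its transporter-mediated drug–drug interactions (DDIs).

Rosuvastatin is the standard clinical probe substrate for hepatic
OATP1B1/OATP1B3 uptake, but it is also carried by intestinal OATP2B1, renal
OAT3 and the efflux pumps BCRP and Pgp, with a minor CYP2C9 metabolic route.
Because unspecific inhibitors such as rifampicin, gemfibrozil and probenecid
hit several of these carriers at once, mechanistic modelling is the
practical way to disentangle clinical DDI study results.  This package is
aimed at pharmacometricians and DDI modellers who want a self-contained,
scriptable rosuvastatin victim model without a GUI platform dependency.

## What is in the model

* **`model_core`** — a stiff ODE system over the organs where the carriers
  act: gut lumen (3 transit segments) → enterocyte → portal vein → liver →
  bile/gallbladder → duodenum (enterohepatic recirculation), kidney → urine,
  plus lumped central and peripheral distribution.  Active processes are
  Michaelis–Menten terms (OATP2B1, OATP1B1/1B3, OAT3, BCRP, Pgp, CYP2C9)
  alongside passive glomerular filtration of unbound drug, GFR·fu·C.
* **`ddi`** — competitive inhibition, Km,app = Km·(1 + I(t)/Ki), driven by
  closed-form perpetrator PK (unbound liver-inlet concentration for hepatic
  uptake, unbound systemic plasma elsewhere), with DDI AUC and Cmax ratios
  judged against the ratio-dependent acceptance envelope of Guest et al.
* **`poppk`** — the two-compartment *split-dose* absorption model that
  describes rosuvastatin's unusually late Cmax: 63.4% of the dose released
  immediately, 36.6% after a 2.3 h lag, both absorbed with the same ka.
  Per-subject multi-start least squares plus a two-stage population summary.
* **`metrics`** — NCA (linear-trapezoid AUC, sampled Cmax/tmax, log-linear
  terminal half-life), mean relative deviation MRD = 10^√(mean Δlog₁₀²),
  geometric mean fold error GMFE = 10^(mean |log₁₀ (pred/obs)|), fractions
  excreted and renal clearance.
* **`calibration`** — multi-start bounded least squares over named model
  parameters with an identifiability (degenerate-direction) guard, and local
  sensitivity coefficients S = (ΔAUC/AUC)/(Δp/p).
* **`synthetic`** — a virtual-study generator (log-normal between-subject
  variability, proportional residual error, LLOQ censoring) standing in for
  the clinical datasets, so the whole pipeline runs offline.

The shipped configuration (`src/rosupbpk/data/rosuvastatin.yaml`) is
calibrated so one parameter set jointly reproduces the compound's published
summary pharmacokinetics: ~20% absolute bioavailability, ~30% of the dose
absorbed, ~90%/~8% of an oral dose recovered in feces/urine, ~37% of an IV
dose in urine, renal clearance ~180 mL/min, tmax ~4–5 h and a ~19 h terminal
half-life.  Every number in the configuration carries a provenance tag
(literature / reference / optimized) and can be overridden.

## Worked example

```python
import rosupbpk as rp

model = rp.load_default_model()

# 40 mg oral dose with the split-dose absorption protocol
result = rp.simulate(model, rp.oral_split(40.0), 240.0)
pk = rp.nca(result.times_h, result.plasma_concentration_ng_per_ml)
ex = rp.excretion_summary(result)
print(f"Cmax {pk.cmax_ng_per_ml:.1f} ng/mL at tmax {pk.tmax_h:.1f} h")
print(f"AUC(0-last) {pk.auc_last_ng_h_per_ml:.1f} ng*h/mL, "
      f"terminal half-life {pk.t_half_terminal_h:.1f} h")
print(f"urine {ex.fe_urine:.3f}, feces {ex.fe_feces:.3f} of dose; "
      f"mass-balance error {result.mass_balance_error():.1e}")

# rifampicin DDI (single-release absorption during co-treatment)
perps, specs = rp.load_default_perpetrators()
ddi = rp.simulate_ddi(model, perps["rifampicin"], specs["rifampicin"],
                      rp.absorption_variant(rp.oral_split(20.0), "rifampicin"),
                      rp.oral_single(600.0), 48.0)
print(f"AUC ratio {ddi.auc_last_ratio:.2f}, Cmax ratio {ddi.cmax_ratio:.2f}")
```

prints

```
Cmax 25.1 ng/mL at tmax 4.5 h
AUC(0-last) 287.0 ng*h/mL, terminal half-life 19.5 h
urine 0.076, feces 0.895 of dose; mass-balance error 6.3e-15
AUC ratio 1.68, Cmax ratio 1.78
```

The plasma profile peaks late (the delayed second release), about 2.8% of
the dose is metabolised, and the mass balance closes to machine precision.
Under rifampicin the exposure rises and — because the dose is released at
once — the peak arrives roughly 1.4 h earlier than under monotherapy.

A command-line interface mirrors the library:

```bash
rosupbpk simulate --dose-mg 40 --out run          # tidy CSV export
rosupbpk ddi --perpetrator rifampicin --out ddi.json
rosupbpk generate --seed 1 --out cohort.csv       # virtual PopPK cohort
rosupbpk poppk-fit --observations cohort.csv --out estimates.csv
rosupbpk evaluate --predictions p.csv --observations o.csv --out table.csv
```

## Layout

```
src/rosupbpk/          library (model, ddi, poppk, metrics, calibration,
                       synthetic, io, cli) + data/ configuration files
tests/                 pytest suite (unit, property and end-to-end checks)
scripts/acceptance.py  headline-result reproduction
docs/methods.md        modelling assumptions, parameter provenance, limits
```
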