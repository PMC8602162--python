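# Methods

## Scope and model structure

The package implements a *reduced* whole-body PBPK model of rosuvastatin:
the full organ-by-organ anatomy of platform PBPK software is collapsed to
the compartments where the drug's carriers act, plus one lumped central and
one lumped peripheral distribution compartment.  Every mechanism with a
distinct observable consequence is retained — carrier-mediated intestinal
uptake and efflux, slow basolateral exit from the enterocyte, hepatic
OATP1B1/1B3 uptake with biliary (BCRP) and metabolic (CYP2C9) elimination,
enterohepatic recirculation, renal OAT3/Pgp secretion and glomerular
filtration of unbound drug — while anatomically unidentifiable detail is
not.  OATP1B1 and OATP1B3 are modelled as a single pooled process: their
reported substrate affinities and rifampicin inhibition constants are too
similar to separate from plasma data, and fitting both rate constants would
only create an identifiability problem.

State variables are compartment amounts in µmol; concentrations are µmol/L
and time is in hours, with converters to mg and ng/mL through the molecular
weight (481.54 g/mol).  Because the blood/plasma ratio (0.56) essentially
equals one minus hematocrit, red-cell partitioning is negligible: all
convective transport uses plasma flows (blood flow × (1 − hematocrit)) with
concentrations expressed on plasma.

Two bookkeeping choices matter for interpretation:

* The gut lumen is represented twice, as a *dosed* pool and a
  *recirculated* pool with identical kinetics.  Biliary outflow and
  gut-wall efflux enter the recirculated pool, so "fraction of the dose
  absorbed" (dose minus dosed-pool feces) is exact and never contaminated
  by recycled drug.
* Biliary drug drains continuously from the gallbladder into the duodenum
  at the bile flow's turnover rate; there are no meal-triggered emptying
  events.

## Physiology

Organ volumes, blood flows, GFR (7.2 L/h), hematocrit (0.45) and bile flow
(0.02 L/h) are an ICRP-style reference adult European male (30 y, 73 kg,
176 cm), shipped as a versioned configuration block and linearly scalable
by body weight.  The central volume (30 L) lumps plasma with rapidly
equilibrating tissues; the peripheral compartment (35 L at partition
coefficient 9.2, exchanging at 20 L/h plasma flow) supplies the deep
distribution phase that, combined with a total clearance near 28 L/h,
produces the ~19 h terminal half-life.  Intestinal transit is 1.0/h per
segment (≈3 h small-intestinal transit over three segments).

## Calibration of the shipped configuration

Measured physicochemistry is fixed at literature values (fu = 0.115, B/P =
0.56, in vitro Km for the hepatic and renal uptake carriers).  Free
parameters — the lumped carrier capacities (vmax), the passive exit from
the enterocyte, the peripheral partition coefficient — were estimated
against the compound's published summary pharmacokinetics for the 73 kg
reference individual: absolute bioavailability ≈ 20%, fraction absorbed
≈ 25%, fecal/urinary recovery ≈ 90%/10% after oral dosing, ≈ 30% urinary
excretion and 227 mL/min renal clearance after IV dosing, tmax ≈ 5 h, and
terminal half-life ≈ 19 h.

These printed values are mutually over-determined: in any model with linear,
route-independent disposition the oral urinary recovery is exactly the
product of bioavailability and the IV urinary fraction, and the well-stirred
liver ties bioavailability to hepatic clearance through F = Fa·(1 −
CL_h/Q_h).  Taken at face value the eight numbers imply two incompatible
hepatic extraction ratios (≈0.2 from F/Fa and ≈0.64 from CL_total), largely
because the 10%-in-urine figure derives from total radioactivity rather
than unchanged drug.  The shipped calibration is therefore a *minimax*
compromise: the four coupled quantities (fraction absorbed, oral urinary
recovery, IV urinary fraction, renal clearance) each sit about 24% from
their printed values — the best jointly attainable — while bioavailability,
fecal recovery, tmax and half-life are essentially centred.

Absorption timing involves one further structural trade-off.  The late
monotherapy peak is produced by the split-dose release protocol (below), on
top of an intrinsic time-to-peak of ≈2.8 h.  In this three-segment cascade
the split-protocol peak can precede the lagged sub-dose's own peak by up to
~1.5 h, so reproducing the ~5 h monotherapy tmax forces the single-release
(DDI-arm) tmax to ≈2.9 h rather than the clinically observed 1.3–2.0 h.
The *switch* — an earlier, higher peak once the delayed release is
abolished — is reproduced and tested; its absolute timing is a known
limitation of the reduced absorption geometry.

Saturable processes use effective Michaelis constants far above the
concentrations attained at clinical doses (for the luminal carriers, far
above luminal concentrations up to 80 mg), consistent with the observed
dose-proportionality of exposure between 10 and 80 mg.

## Split-dose population PK model

The unusually slow absorption phase is described compartmentally: a
two-compartment disposition model in which a fraction `1 − f_second` of the
oral dose is absorbed immediately and `f_second` after a lag, both with the
same first-order ka.  The final parameterization uses the population
medians f_second = 0.366 and lag = 2.3 h; disposition constants (CL/F
141 L/h, V1/F 225 L, V2/F 1880 L, Q/F 140 L/h, ka 0.45/h) are package
defaults chosen to match the compound's exposure, peak time and terminal
half-life at 40 mg.  During rifampicin or probenecid co-treatment the whole
dose is released at once with no lag; gemfibrozil arms keep the split.
DDI covariate factors multiply bioavailability and clearance.

Estimation is deliberately simpler than nonlinear mixed-effects modelling:
stage one fits each subject by multi-start Levenberg–Marquardt least squares
on log concentrations (all parameters transformed to an unconstrained
scale; starts drawn log-uniformly within e^±0.5 of the initial values);
stage two takes component-wise medians and log-scale SDs across subjects.
Two conventions keep the per-subject problem well posed:

* ka is fixed at its population value during cohort refits (the virtual
  cohorts carry no between-subject variability on ka);
* the fixed dispersion constants V2/F and Q/F are rescaled by the fitted
  V1/F relative to its initial value, so a subject-level bioavailability
  shift — which scales *all* apparent volumes and clearances equally —
  remains inside the fitted family.

Structural absorption-model choice (split vs single) uses a small-sample
information criterion (AICc on the log-residual SSE; the split model pays
for its two extra parameters), with ties broken towards the single model.

## Synthetic virtual studies

The generator emulates the statistical structure of the clinical datasets
the analysis assumes: one mean virtual individual per study; median-
preserving log-normal interindividual variability on named parameters;
proportional residual error applied as exp(N(0, σ)) on each plasma sample;
censoring below the LLOQ.  Defaults: σ = 0.2 (20% proportional error), CV =
20% on the delayed-dose fraction and 30% on bioavailability and clearance —
absorption-fraction variability is typically reported smaller than
clearance variability for this compound class.  The default 14-point plasma
sampling grid spans 0.5–96 h and is dense over 0.5–4 h so that it brackets
the 2.3 h release lag; a grid without samples between 2 and 4 h cannot
identify the lag per subject (estimates pile up on the nearest sample
time).  Cumulative urine/feces collection runs to 240 h, by which point the
linear-regime mass balance is closed to better than 0.1%.

What the generator does *not* emulate: real between-study heterogeneity in
design and assay, covariate distributions (all subjects share the reference
physiology scaled by weight), between-occasion variability, and model
misspecification — the refits estimate the same structural model that
generated the data.  Passing recovery tests therefore demonstrates that the
estimator is consistent and the pipeline is wired correctly, not that the
model family is correct for real patients.

## DDI engine

Perpetrators are closed-form 1–2-compartment PK models (superposition over
doses); their parameter sets are coarse literature-informed defaults, since
perpetrator fidelity is not the modelled content.  Competitive inhibition
enters as a time-varying apparent Km on each targeted process,
Km·(1 + Σᵢ Iᵢ(t)/Kiᵢ), summing contributions when a parent and its
metabolite (gemfibrozil and its 1-O-β-glucuronide, at a default 30% molar
ratio) act on the same carrier.  Hepatic uptake inhibition is driven by the
unbound liver-inlet concentration (systemic plasma plus the ka·A_gut/Q_portal
first-pass term); renal and intestinal processes use unbound systemic
plasma.  Because the intestinal driving concentration is systemic rather
than luminal, the default rifampicin Ki on OATP2B1 is scaled up (17 µM);
an in-vitro-scale value under this convention would make intestinal uptake
inhibition cancel the hepatic interaction and invert the known net effect.
The rifampicin OATP1B1/1B3 Ki is the published 0.63 µM (0.29 µM is the
cited alternative).  All arms are competitive-inhibition only: no
induction, no mechanism-based inactivation.

DDI ratios are AUC_last and Cmax of the treated over the control arm on a
common window from victim dose time to the simulation end.  The prediction
success envelope follows Guest et al.: L(R) = (1.25 + 2(R − 1))/R with
limits (R/L, R·L) for R ≥ 1, applied symmetrically on the reciprocal below
one — the two-fold criterion at strong interactions, tightening to the
0.8–1.25 bioequivalence band at unity.

## Numerics

* Integration: `scipy.integrate.solve_ivp` (LSODA), rtol 1e−8 / atol 1e−10
  by default; every dose and infusion boundary restarts the integrator so
  state discontinuities never cross a solver step.  Oral boluses enter the
  first lumen segment; IV boluses enter central plasma.
* Mass balance (compartments + sinks vs cumulative administered amount) is
  checked point-wise; the shipped model closes to ~1e−14 relative.
* AUCs use the linear trapezoid (a log-down variant is available);
  internal AUC-based quantities (renal clearance, sensitivity
  coefficients) use dense-early output grids because bolus-like fronts
  otherwise bias the trapezoid by a parameter-independent amount.
* Calibration uses `least_squares(method="trf")` — trust-region steps of
  Levenberg–Marquardt character that honour box bounds — with seeded
  multi-start (default 10 log-uniform starts); per-subject PopPK fits use
  the unbounded `method="lm"` on transformed parameters.  A fit reports the
  number of near-degenerate Jacobian directions (relative singular value
  below 1e−6) as an identifiability warning.
* Loss: squared log10 residuals on plasma concentrations (equalising the
  0.002–80 mg dosing range), squared linear residuals on excretion
  fractions; below-LLOQ observations are excluded.
* Terminal half-life: least squares on ln C over all samples past 24 h, or
  the last four samples, whichever set is larger.
* Observed Cmax/tmax are the sampled maximum without interpolation,
  matching digitised-data practice.

## Problem sizes

Default analyses use a single virtual individual per arm; simulations run
to 240–500 h for mass-balance closure (≥7 terminal half-lives); virtual
PopPK cohorts use 32 subjects × 14 samples; calibration demonstrations use
one to three studies with ≤10 observations each and ≤10 multi-start
repeats.  These sizes were chosen so every analysis is exactly reproducible
on a laptop in minutes.

## Known limitations

* No metabolite PBPK; CYP2C9 products leave the system as a sink.
* Perpetrator PK is deliberately coarse; multiple-dose rifampicin induction
  and cyclosporine/ritonavir interactions are out of scope.
* The single-release (DDI-arm) simulated tmax is ≈2.9 h against observed
  1.3–2.0 h (see the calibration section).
* The reduced physiology cannot represent tissue-level readouts (e.g.
  imaging-derived organ concentrations) beyond the lumped liver and kidney
  amounts.
* Two-stage population estimates ignore shrinkage; with sparse per-subject
  data they will be noisier than a mixed-effects estimator.
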