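# Methods

## Scope

`atezopk` simulates extended-interval IV dosing of atezolizumab in a
virtual oncology population and summarizes per-cycle exposure. It is a
simulation and non-compartmental-summary tool only: it does not estimate
model parameters, and it simulates noise-free model predictions (no
residual error, no BLQ handling).

## Virtual population

Each subject is drawn independently:

| covariate | model | default |
|---|---|---|
| age | Uniform(age_min, age_max) | 20–80 yr |
| sex | Bernoulli(p_male) | p = 0.5 |
| weight | intercept(sex) + 0.75·(age−40) + N(0, sd(sex)²) | F: 65 kg, sd 3.5; M: 85 kg, sd 10 |
| albumin | exp(N(ln 42, 0.10²)) g/L | median 42 g/L |
| tumor size | exp(N(4.2, 0.70²)) mm | median e^4.2 ≈ 66.7 mm |
| ADA | Bernoulli(p_ada) | p = 0.40 |

The age distribution is taken as continuous uniform (the simplest model
consistent with the observed medians near 50 and the stated range). The
weight-noise second arguments are standard deviations in kg. The ln-scale
SDs of albumin (0.10) and tumor size (0.70) are calibrated so that the
min–max range of 1000 draws matches the published demographics table when
read as extreme order statistics; both are exposed in the config. A
physiological floor (weight > 20 kg) is enforced by redrawing the noise;
at the default SDs this is never triggered in practice.

Each covariate consumes an independent spawned RNG substream from one
master seed, so adding or removing a column never perturbs the others and
every table is bit-reproducible.

The generator emulates the marginal structure of a reported demographics
table, not a real trial population: covariates other than the stated
age→weight dependence are independent, there are no renal/hepatic
covariates, no correlation between albumin and tumor burden, and no
enrollment-driven skew. Passing tests therefore validate the simulation
machinery and summary statistics, not covariate realism.

## PK model

Linear two-compartment disposition with IV-infusion input, parameterized
as CL, V1, Q, V2 (L/day, L). Covariates act multiplicatively: power models
`(x/ref)^θ` for continuous covariates, proportional shifts `1+θ` for
binary flags (applied when the flag is set); effects compose
multiplicatively and are order-independent. Between-subject variability is
log-normal, `param_i = typical·exp(η)`, η multivariate normal with
variances ω² per parameter and an optional correlation matrix (identity by
default; the matrix is validated symmetric PSD with unit diagonal).
Clearance is time-invariant, matching the linear model class simulated.

The shipped default config transcribes the published atezolizumab popPK
model (CL 0.200 L/day, V1 3.28 L, Q 0.546 L/day, V2 3.63 L; weight,
albumin, tumor-burden, ADA and sex effects on CL; weight and sex on V1;
ω²_CL = 0.083, ω²_V1 = 0.0324). These numbers are configuration sourced
from the external publication, clearly annotated in the YAML; the test
suite's correctness checks use independent documented values so nothing
depends on the transcription.

## Dosing

A regimen is an ordered list of blocks (amount mg, interval days,
n doses). Built-ins: 1200 mg q3w ×7 and three extended arms (840 q2w /
1200 q3w / 1680 q4w loading ×2, then 840 mg q6w ×5). Crossing a block
boundary, the gap before the first dose of the new block equals the *new*
block's interval — "loading followed by q6w" puts the first maintenance
dose 42 days after the last loading dose. Cycle window k runs from dose k
to dose k+1 (the last window spans one final interval); windows partition
[0, end) exactly. Infusions default to 1 hour (1/24 day), configurable;
for a drug with a multi-week half-life the infusion/bolus distinction
shifts exposure metrics by <0.1%, but it is kept explicit for the
NONMEM-style export. All times are days; a week is 7 days.

## Engine numerics

The closed form is the production path; the ODE integrator
(`scipy.integrate.solve_ivp`, DOP853, rtol 1e-12, with integration split
at every infusion start/end so no discontinuity is stepped over) is the
verification oracle and the route for user-supplied nonstandard models.
Both share the event expansion. Numerical choices:

* **Observation grid** — each cycle carries its start, points every
  0.1 day (configurable), its end (the trough time) and the end-of-infusion
  time, where Cmax is attained. This yields ~141 observations per subject
  for a 14-day cycle and ~1.5–2.8 million observations per 1000-subject
  regimen.
* **Degenerate roots** — q = 0 selects a one-compartment branch
  (α = k10, β = 0). A confluent biexponential (|α−β|/α < 1e-10) is
  evaluated by nudging β apart by 1e-7 relative, bounding the cancellation
  error near 2e-9 — well inside the 1e-6 oracle-agreement budget.
* **β via Vieta** — β = (k10·k21)/α rather than the subtractive root,
  avoiding cancellation when k10·k21 is small.
* **Dose-time convention** — the concentration at a dose time is the
  pre-dose trough (an infusion contributes nothing at its own start);
  the rising edge begins immediately after.
* **Steady-state trough** — closed geometric-series accumulation of the
  per-phase single-dose terms; verified against explicit brute-force
  superposition with the dose count scaled to the terminal half-life so
  the truncated tail is < 1e-12.

## Exposure metrics

Per cycle: Cmax is the maximum over the window; Cmin is the value at the
window end (the pre-next-dose trough — for these monotone-tailed profiles
identical to the within-cycle minimum after the peak); weekly AUC is
trapezoidal AUC over the window × 7/window-length, the only AUC scale
comparable across 14/21/28/42-day intervals. Population summaries use
exp-mean-log geometric means (nonpositive values are an error, never
dropped) and linear-interpolation percentiles (numpy's default rule),
with the 90% prediction interval reported as [p5, p95]; the fixed quantile
rule makes all bands bit-reproducible. With the 0.1-day grid and the
end-of-infusion point included, the trapezoidal cycle AUC is within 1e-4
of the analytic integral; without that point the kink at the end of a
1-hour infusion costs ~0.4%.

## Problem sizes and determinism

The shipped study configuration is 4 regimens × 1000 subjects × 7 cycles
at the 0.1-day grid (1.48–2.81 million observations per regimen); the full
pipeline, including summaries and eight figures, runs in a few seconds on
one CPU and is byte-identical across reruns with the same seed. Test-suite
simulations use smaller populations (50–300 subjects) and coarser grids
where the property under test does not require study scale; the
oracle-vs-closed-form sweep uses 100 random parameter sets over all four
regimens at a 3-day grid.

## Known limitations

* Exposure summaries inherit ~2% downward bias at "steady state" because
  cycle 7 is only ≈98% accumulated for a 26-day terminal half-life; this
  mirrors the study design (7 cycles) rather than true steady state, which
  the `steady_state_trough` closed form provides exactly.
* Subjects in the extreme slow-clearance tail of the IIV distribution
  retain >3% loading-dose memory at cycle 7, so the three extended arms'
  cycle-7 metrics converge as population summaries and for typical
  subjects, not uniformly per subject.
* The transcribed default PK parameters reproduce the published cycle-7
  q3w weekly-AUC geometric mean to ~0.3% (just below the narrow range
  spanned by the three published software columns); exact agreement would
  require the original model files, which are not distributed with the
  source publication.
* No target-mediated or nonlinear elimination, inter-occasion variability,
  dose individualization (mg/kg), missed doses, or non-IV routes.
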