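# Methods

`phycosat` implements a complete photophysiology analysis for 9-day
macroalgal culture experiments instrumented with PAM fluorometry and a
minute-resolution PAR logger, together with a seeded synthetic-study
generator that reproduces the statistical structure the analysis assumes.
This note records the models, the numerical choices, and what the generator
does and does not emulate.

## Photosynthesis–irradiance model

Each rapid light curve (RLC) steps a plant through nine actinic irradiances
(0, 65, 90, 125, 190, 285, 420, 625, 820 μmol photons m⁻² s⁻¹) and records
the effective quantum yield Φ_PSII at each step.  Yields are fitted with the
exponential-saturation (Webb) model in irradiance-normalized form,

    Φ(E) = α · (E_k / E) · (1 − exp(−E / E_k)),    Φ(0) ≡ α,

which avoids the intrinsic irradiance dependence of yield measurements.
Parameters: α, the light-limited efficiency (dimensionless, yield scale),
and E_k, the saturation irradiance (μmol photons m⁻² s⁻¹).  The maximum
photosynthetic rate is P_max = α·E_k (μmol electrons m⁻² s⁻¹), stored as the
exact product of the fitted values.

Numerical choices:

* The E = 0 step is kept in the fit via the analytic limit Φ(0) = α; the
  limit is exact and all nine instrument levels are preserved.
* Bounded trust-region least squares on Φ (unweighted — the normalization
  is itself the variance stabilization), bounds α ∈ (10⁻⁶, 2],
  E_k ∈ (10⁻³, 2000], tolerances 10⁻¹² on cost, step and gradient, starting
  from α₀ = Φ at the lowest nonzero irradiance and E_k0 = the irradiance at
  which Φ first falls below α₀/2 (fallback 100).  On noiseless 9-point
  curves this recovers α to ≲10⁻¹² and E_k to ≲10⁻⁹ across
  (α, E_k) ∈ (0, 1] × [5, 300].
* Non-convergence is reported in the result (`converged=False`), never as an
  exception.  A curve with no positive yield — the depigmented-individual
  case — raises `UnfittableCurveError`, and the pipeline excludes that
  replicate from all downstream tables with a logged reason.
* rETR_max is the largest E·Φ product among steps with Φ_PSII > 0.1 (the
  screen that keeps fluorescence-based ETR in the range where it tracks
  oxygen evolution); with no qualifying step it is missing.  Exact ties on
  the product resolve to the lower irradiance, the conservative side away
  from any photoinhibited plateau.  rETR_max is report-only; all downstream
  analysis uses P_max.

## Irradiance reductions

The logger records PAR once per minute from 05:00 to 19:30.

* **Condensed series**: a trailing 10-minute moving average (the window ends
  at the labelled minute; shorter windows at the series start use the
  available samples) kept only at clock minutes :00, :10, …, :50.
* **Day length**: 10 min × the number of condensed samples with
  E ≥ 1 μmol photons m⁻² s⁻¹.
* **H_sat**: per-day count of *raw* minutes with E ≥ the plant's E_k — the
  condensation applies only to day length.  Day 1 is truncated to start at
  the plant's first RLC and day 9 to end at its last (experiments start at
  08:00 on day 1 and finish by noon on day 9); intermediate days use the
  full logged span.  Windows beyond the logged span are clipped with a
  warning.
* **Period mapping**: plants are measured on days 1, 5 and 9 only, so E_k is
  assigned by period — days 1–3 use the D1 fit, days 4–5 the D5 fit, days
  6–9 the D9 fit.  A `no_d5` scheme (days 1–4 ← D1, days 5–9 ← D9) covers
  runs where the mid-point measurement was not taken.
* **Summaries**: the per-plant H_sat is the mean of the three period means
  (equal period weights — the periods span 3, 2 and 4 days).  The wording of
  this average is genuinely ambiguous between period means and a plain mean
  over the nine days, so `all_days` is exposed as a config switch; the
  default is `period_means`.  rel-H_sat similarly averages per-day
  percentages 100·H_sat(day)/day-length(day) rather than taking a ratio of
  means; days with zero day length are excluded with a warning.

## Production indices

    daily DSPI = P_max(period of day) · 60 · H_sat(day) · 10⁻⁶   [mol m⁻²]

(60 converts P_max from per-second to per-minute; 10⁻⁶ converts μmol to
mol).  The final DSPI is the mean of the daily values (`daily`); a
`period_means` mode mirrors the H_sat switch.  The index deliberately omits
respiration and any non-irradiance loss: it is an irradiance-only ceiling on
daily gross production.

Growth over the 9 days is 100·((w_f − parasite) − w_i)/w_i on wet weights,
with the biomass of any epiphytic parasite removed at final weighing
deducted from w_f.

## Mixed-model layer

Every response (P_max, E_k, H_sat, rel-H_sat, DSPI, growth) is modelled with
treatment and temperature as categorical fixed effects (references T0 and
20 °C) and random intercepts for plant ID, run, RLC measurement order and
lunar phase.  The random terms are crossed, so they enter as variance
components over a single all-rows grouping (statsmodels `MixedLM`).  All
fits are maximum likelihood — REML likelihoods are not comparable across
fixed-effect structures — and every p-value is a likelihood-ratio test
against the null lacking the tested effect: χ² = 2(ℓ_full − ℓ_null) clipped
at zero, df = the fixed-parameter difference (4 for a 5-level treatment, 2
for temperature), p from the χ² upper tail, no multiple-testing correction.

A fit whose variance component collapses to the boundary (≤ 10⁻⁴ × residual
variance) is flagged singular; offending terms are dropped and the model
re-fitted in the fixed order lunar phase → RLC order → run.  The plant-ID
intercept is never dropped.  Goodness of fit is reported as
Nakagawa–Schielzeth R² for Gaussian models: R²m = σ²_f/(σ²_f + Σσ²_r + σ²_e)
and R²c = (σ²_f + Σσ²_r)/(same denominator), with σ²_f the population
variance of the fixed-effect predictor.

Growth is additionally regressed on each of P_max, E_k, H_sat and DSPI
separately (ordinary least squares, t-test p-values), and the growth–DSPI
relationship is refitted as an LMM with a random intercept for treatment
plus an LRT on the slope.  With a single treatment level that model falls
back to simple regression with a warning.

One structural reading is worth recording: the analysis table has one row
per replicate, so a replicate-level "plant" intercept would be confounded
with the residual.  Source plants are sectioned into four replicate pieces
spread across treatments, and the plant-ID random effect refers to that
source plant; this makes the component identifiable and keeps plant
variation crossed with treatment rather than nested in it.

## Synthetic-study generator

The generator emulates the experiment's structure: six salinity/nutrient
treatments (T0: 35‰/0.5 μM N/0.005 μM P through T4: 11‰/80.0/3.79, including
the intermediate T2.5: 28‰/52.9/1.64) × three temperatures (20/27/30 °C) ×
16 replicates per cell and species.  The base treatments share eight runs of
two replicates per cell; the later-added T0 and T2.5 cells occupy their own
runs with one piece per collected plant.  Exclusion switches flag (never
delete) the entire green-alga T2.5 cell and two depigmented red-alga
individuals, leaving 240 and 286 analyzable observations.

Per-plant truth is cell mean + source-plant intercept + replicate intercept
(+ optional day drift), truncated to α ∈ [0.02, 0.95] and E_k ≥ 5.  The
mean surfaces are calibrated to the study's reported treatment means of D9
P_max and E_k per species (the green alga rising from P_max ≈ 31/E_k ≈ 27 at
T0 to ≈ 74/110 at T4; the red alga nearly flat across treatments), with
centred temperature offsets (the red alga ~17–19 units of P_max and ~36–39
of E_k lower above 20 °C).  The implied T0 α exceeds the physical yield
ceiling (a mean-of-ratios artifact in the calibration source), so α is
truncated at 0.95; this lowers the generated absolute T0 P_max but affects
no ordering the tests assert.  RLC yields are Webb values + Gaussian noise
(SD 0.01, a typical PAM yield repeatability) clipped to [0, 1].

Irradiance is a half-sine clear-sky profile on a daylight window drawn
uniformly from 611–688 min (the study's seasonal range), centred in the
logging window, scaled by a 0.5 shade-cloth factor from a 700 μmol m⁻² s⁻¹
clear-sky peak (a free configuration value), with per-minute multiplicative
lognormal cloud noise (σ = 0.2).  Growth is linear in true DSPI
(slope 12.2 %/unit for the green alga, 4.1 for the red, matching the
reported growth–DSPI coefficients) plus a per-treatment random effect
(SD 5) and residual noise (SD 8); initial weights are uniform on
0.28–0.30 g.

All draws flow from one study seed in a fixed order (design → plant
parameters → RLC yields → irradiance → growth) through spawned NumPy
generator streams, so studies are bit-reproducible.

What the generator does **not** emulate: mechanistic nutrient uptake or
salinity physiology (treatment effects are injected directly into the mean
surfaces), non-photochemical quenching, respiration, tidal or lunar
coupling of irradiance, within-day temperature dynamics, and realistic
cloud autocorrelation (cloud noise is i.i.d. per minute).  Passing tests
therefore demonstrate that the *analysis* recovers structure the data
contain — not that real plants behave like the generator.

## Calibration of the statistical layer

Two Monte-Carlo checks calibrate the model layer at a reduced problem size
(5 treatments × 3 temperatures × 4 replicates = 60 rows, chosen to keep the
suite fast while leaving enough levels for every factor):

* **Type-I error**: 500 null studies (no treatment effect; plant and
  residual variation only) give a treatment-LRT rejection rate of ≈ 0.05–
  0.07 at p < 0.05.  The χ²-based LRT is mildly anticonservative at n = 60
  (the exact-OLS analogue gives 0.074), and a run variance component cannot
  be estimated from the three runs this reduced design contains, so the
  null fits use the plant intercept alone.
* **Coverage**: the growth~DSPI mixed model's Wald 95% CI covers a known
  generating slope in ≈ 95% of 200 simulations.

## Known limitations

* The LRT uses the asymptotic χ² reference; at small n it is slightly
  liberal, and no Kenward–Roger/Satterthwaite small-sample correction is
  provided.
* Variance components at the boundary make Wald standard errors of the
  random structure unreliable (fixed-effect LRTs are unaffected); singular
  fits are flagged rather than repaired beyond the documented drop order.
* DSPI assumes photosynthesis runs at exactly P_max throughout H_sat and at
  zero outside it; it is a comparative index, not a production estimate.
* Time is wall-clock local, in integer minutes; no timezone or solar
  astronomy is attempted.
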