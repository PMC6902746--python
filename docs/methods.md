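# Methods

## The accumulation model

The latent amyloid level A(t) of every simulated participant solves the
bounded logistic ordinary differential equation

    dA/dt = r (A − L)(U − A),        L < A < U,

whose closed form is implemented in `logistic_level`.  The instantaneous
rate, viewed as a function of the current level, is an inverted U peaking at
(L + U)/2 with height r (U − L)²/4; the level itself is a sigmoid in time.
Defaults are L = 1.1, U = 2.5 (SUVR), r = 0.112 /(SUVR·yr), so the rate
peaks at SUVR 1.8 with ~0.055 SUVR/yr.  These are calibration constants: the
asymptotes bracket the observed composite-SUVR range in elderly cohorts
(~1.1 in amyloid-negative individuals, ~2.5 near saturation) and r is set so
the peak rate matches the magnitudes seen in serial PiB studies.

Because participants are observed at a baseline and one follow-up visit, the
quantity the analysis actually estimates is the *chord-average* rate
(A(t) − A(0))/t, not the instantaneous rate.  Averaging over a finite
interval shifts the peak slightly left of (L+U)/2 — by ≈0.03–0.07 SUVR for
intervals of 1.2–2.4 y under the defaults — so fitted peak locations near
1.75 are the expected behaviour of the design, not an estimation error.

## The synthetic cohort

`generate_cohort` emulates a matched amyloid-PET cohort:

* **Groups.** 35 cases (a mild probable-DLB-like group) and a configurable
  control pool (default 1000) of cognitively-unimpaired-like participants.
  Latent baseline levels are truncated normals inside (L, U): cases
  mean 1.58, SD 0.41; controls mean 1.36, SD 0.22.
* **Composition.** Ages ~ N(69.6, 7.3) in both groups; sex (male fraction
  31/35) and APOE ε4 carriership (16/35) are assigned by exact count —
  evenly spread deterministic flags, not Bernoulli draws — so integral
  compositions are reproduced exactly.
* **Visits.** Observational mode: baseline at t = 0 plus one follow-up at a
  group-specific truncated-normal interval (cases 1.2 ± 0.4 y, controls
  2.4 ± 1.0 y, minimum 0.5 y).  Trial mode: a fixed schedule of visit times
  passed explicitly.  Observed SUVR adds N(0, 0.02) measurement noise; the
  within-person SUVR test–retest SD is not well pinned down in the
  literature, so 0.02 is a configurable default.
* **Clinical decline.** Each measure changes linearly with a per-participant
  slope
  `intercept + c_base·A0 + c_rate·ΔA/yr + N(0, residual_sd)`, where A0 and
  ΔA/yr are the *latent* baseline level and annualized change.  The nonzero
  couplings use published simple-regression coefficients as generative
  truths: DRS −22.40, CDR-SOB +1.90, BNT −2.39, TMT-A +43.43 per unit
  baseline SUVR; AVLT delayed recall −25.05 per unit ΔSUVR/yr.  MMSE,
  UPDRS-III and RCF are uncoupled (no association was found for them), which
  also makes their association p values exactly uniform under the null.
  Each measure loads on a single predictor so that the simple-regression
  stage recovers its coupling without omitted-variable bias.  Intercepts are
  anchored so the control group (A0 ≈ 1.36, ΔA ≈ 0.016/yr) is approximately
  stable; with those anchors the case group declines at clinically plausible
  rates (e.g. DRS ≈ −5/yr, TMT-A ≈ +10 s/yr).
* **Measurement noise on scores.** Beyond the slope residual the generator
  supports per-visit score noise (`measurement_sd`, defaults of 0.5–8 points
  by scale).  This term is what makes the residual variance of the mixed
  model identifiable in multi-visit trial simulations; setting it to 0
  recovers the pure two-visit slope model.
* **Baseline score distributions** are per-group (cases from the published
  baseline table; control values for DRS/BNT/RCF, which were not reported,
  are plausible healthy-elderly constants: 140.5 ± 2.5, 27.5 ± 2.0,
  32 ± 3).  Baselines are clipped to each scale's range; follow-ups are not
  clipped, preserving the linear slope model.
* **Missingness.** An optional missing-at-random mask per measure
  (default off).

What the generator does *not* emulate: practice effects, floor/ceiling
compression of follow-up scores, informative dropout, diagnostic
misclassification, or any image-level process.  Passing tests therefore
demonstrate that the *pipeline* recovers what this data-generating process
encodes, not that the published cohort's numbers would be reproduced.

## Matching

Greedy nearest-neighbour without replacement: cases in ascending id order;
candidates restricted to the exact sex × APOE stratum and a 3-year age
caliper; ties in |age difference| broken by ascending control id.  This is
deterministic and seed-free.  The procedure errors (naming the case and
stratum) if a case cannot be fully matched, unless `allow_partial` is set.
Frequency matching and optimal (network-flow) matching are out of scope.

## Rate curve

`RateCurveModel.fit` solves the penalized least-squares problem

    min ‖y − Bβ‖² + λ βᵀDᵀDβ

with B a cubic B-spline basis on *equidistant* knots extending three
spacings beyond the observed baseline-SUVR range (20 interior knots by
default) and D the second-order difference operator.  Equidistant knots make
the Greville abscissae equidistant, so the penalty's null space is exactly
the straight lines in x: linear signals pass through unshrunk at any λ.
λ is found by bisection on log λ so that the effective degrees of freedom —
tr[(BᵀB + λDᵀD)⁻¹BᵀB] — equal the target (4.0 ± 0.01 by default, the
fixed-edf analogue of a "4-df penalized spline").  Smoothness is fixed, not
selected by GCV/REML, to keep every fit at the same flexibility.

Uncertainty uses the frequentist sandwich
σ̂² (BᵀB+λP)⁻¹ BᵀB (BᵀB+λP)⁻¹ with σ̂² = RSS/(n − edf); pointwise 95% bands
are ±1.96 SE.  Penalized bands ignore smoothing bias, so their average
pointwise coverage sits slightly below nominal (≈0.91–0.92 at n = 300 in the
test suite's simulations).  Predictions outside the observed baseline range
are refused — the data are sparse above SUVR ~1.7 and extrapolated rates
would be pure penalty artefacts.

## Group tests

* **Shape difference** — nested OLS with fixed 4-df natural cubic regression
  splines (boundary knots at the pooled range, interior knots at the pooled
  quartiles): common curve (5 parameters) vs group intercept +
  group-specific curves (10 parameters); analysis-of-deviance F with
  (5, n − 10) df.
* **Vertical shift** — one common penalized curve (edf 4, calibrated on the
  smooth alone) plus an unpenalized group indicator; the indicator's
  estimate (SUVR/yr, positive = cases accumulate faster), sandwich SE and a
  t reference with n − total edf denominator df.
* **Linearity** — straight line vs the 4-df regression spline, F with
  (3, n − 5) df.

Under null simulations all three are calibrated (type-I error 0.05 ± 0.02
over 500 replicates in the suite).  The matched design enters the group
comparison only through this indicator; block-level random effects are a
documented simplification not implemented.

## Trajectory integration

`RateCurveResults.integrate` solves dA/dt = max(f̂(A), 0) with classical RK4
on a fixed step (default 0.05 y) from a start level (default: 2.5th
percentile of observed baseline SUVR), stopping at `t_max`, when the rate
drops below ε = 1e-4 SUVR/yr, or when the level would leave the fitted
range.  Negative fitted rates are clipped to zero *only* during integration:
the cumulative curve is a level process, while the displayed rate curve may
legitimately dip below zero.  RK4 reproduces the closed-form logistic to
<1e-10 at step 0.05 on the exact quadratic law.

## Associations and blocked comparisons

Association models are unadjusted simple OLS regressions (complete-case) of
each annualized clinical change on one predictor at a time — baseline SUVR
or SUVR change — reported as coefficient, SE, two-sided p, R² and n.  No
multiplicity correction is applied, matching standard practice for this kind
of descriptive table; covariate adjustment (age, sex, education, APOE) is
available via the `covariates` argument but off by default.  Whether
outcomes should be transformed is left to the caller; defaults are
untransformed.

Baseline group comparisons use a randomized-block two-way fixed-effects
ANOVA (`value ~ group + block`) with the matching block as the added
predictor.  Skewed baselines can be normalized first: log for baseline SUVR,
√x for CDR-SOB (zeros present), √(30 − x) for MMSE (ceiling at 30) — the
transform-variable assignment is configurable since it is a convention, not
a deduction.  With a single block the test reduces exactly to one-way ANOVA.

## Trial sample sizes

`fit_lmm` fits y_ij = (β₀+u0ᵢ) + (β₁+u1ᵢ)t_ij + ε_ij with unstructured 2×2
random-effect covariance by REML (statsmodels MixedLM; several optimizers
are tried because near-boundary variance components defeat single line
searches).  Exactly collinear noiseless data short-circuit to the OLS line
with zero variance components, where REML is undefined.

`required_n` implements the one-sided two-arm slope-reduction closed form
above with the normal (z) approximation — matching the "asymptotic" framing
— and returns the *unrounded* n; ceilings are display-only, so
n(25%)/n(50%) = 4 exactly.

`sample_size_table` simulates the case arm once on the master reading
schedule {0, 12, 18, 24, 36} months (the trial enrols patients, so only the
case-like generator arm is used), estimates variance components per outcome
by leave-one-subject-out jackknife on that dataset, and lets each follow-up
duration enter through its cumulative schedule's Sₓₓ (12 mo → readings
{0,12}; 18 → {0,12,18}; 24 → {0,12,18,24}; 36 → {0,12,18,24,36}).  Two
consequences are then analytic rather than stochastic: per-arm n is
nonincreasing in duration, and the 25%/50% ratio is exactly 4 in every
jackknife replicate.  Estimating components per duration dataset instead
would leave both properties to sampling noise and make the two-visit
12-month cell unidentifiable (random slope and residual cannot be separated
with two observations per subject).  The jackknife reports the replicate
mean with the asymptotic CI mean ± 1.96·SE, SE² = (m−1)/m Σ(nᵢ − n̄)²;
non-converged replicates are dropped (error if more than 20%), and the CI's
lower limit is truncated at 0 since a heavy-tailed replicate distribution
(slopes near zero inflate nᵢ ∝ 1/β₁²) can otherwise push it negative.
No dropout is modelled (a per-visit retention hook exists in the design but
defaults to full retention).

## Reproducibility

All randomness flows from a single seed.  The pipeline derives one
substream per stage by hashing the stage name into a `SeedSequence`
(`stage_seed`), so stages can be rerun in isolation; with a fixed seed,
`run-all` is byte-identical across runs (SHA-256 manifest).  CSV is used
for all tabular artifacts (full float precision, empty string for missing)
and JSON for model objects.

## Problem sizes used in the shipped analyses

The test suite and acceptance script use desk-scale cohorts chosen to make
each property measurable: 35 cases + 1000-control pool for matching; 1000
participants for rate-curve estimation (the peak location stabilises to
±0.02 SUVR there); 500 null replicates at n = 200/group for test
calibration; n = 2000 with reduced residual noise for coefficient recovery;
35 subjects on the 5-visit master schedule for the sample-size grid.

## Known limitations

* The rate curve is a single-smooth Gaussian model; non-Gaussian families
  and multi-term additive models are out of scope.
* Pointwise bands undercover slightly under smoothing bias (see above).
* The group comparison conditions on matching via an indicator; it does not
  model within-block correlation.
* Sample-size estimates inherit the synthetic cohort's variance components;
  they demonstrate the machinery, not a clinical recommendation.
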