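# amytraj

Longitudinal β-amyloid (PiB-PET SUVR) trajectory analysis for matched
case–control cohorts, with a focus on dementia with Lewy bodies (DLB).

Serial amyloid-PET studies consistently find that the *rate* of β-amyloid
accumulation, plotted against the *current* amyloid load, forms an inverted
U: accumulation accelerates at low load, peaks mid-range (around a composite
PiB SUVR of ~1.8), and decelerates as the load saturates.  Integrated over
time, the load itself follows a sigmoid.  `amytraj` implements the full
analysis pipeline built around that observation:

1. **Cohort simulation** — a generator for matched case–control longitudinal
   data (two groups, 4:1 matched on age, sex, APOE ε4; group-specific
   baseline SUVR distributions and interscan intervals) whose latent amyloid
   level solves the bounded logistic law dA/dt = r (A − L)(U − A) and whose
   clinical scores decline at rates coupled to amyloid load and its change.
2. **Matching** — greedy nearest-age 4:1 matching without replacement, exact
   on sex and APOE ε4, within an age caliper.
3. **Rate-curve estimation** — annualized SUVR change regressed on baseline
   SUVR with a cubic P-spline (second-order difference penalty) whose
   penalty weight is chosen by bisection so the effective degrees of freedom
   (trace of the smoother matrix) equal a fixed target, 4 by default;
   pointwise 95% bands; no extrapolation beyond the observed range.
4. **Group tests** — analysis-of-deviance F tests with fixed 4-df natural
   cubic regression splines (common curve vs group-specific curves; line vs
   spline) and an additive group-offset test on a common penalized curve.
5. **Trajectory integration** — classical 4th-order Runge–Kutta integration
   of the fitted (nonnegative-clipped) rate curve into a cumulative
   SUVR-vs-time sigmoid.
6. **Clinical associations** — simple linear regressions of each annualized
   clinical change (CDR-SOB, MMSE, DRS, UPDRS-III, AVLT, BNT, TMT-A, RCF) on
   baseline SUVR and on SUVR change, plus randomized-block ANOVA baseline
   comparisons honouring the matching.
7. **Trial sample sizes** — random-intercept/random-slope linear mixed
   models (REML) and leave-one-subject-out jackknife resampling give per-arm
   sizes for two-arm trials powered to detect a 25% or 50% reduction in the
   mean slope of decline:

   n/arm = 2 (z₁₋α + z_power)² (σ²_slope + σ²_ε / Sₓₓ) / (Δ·β₁)²,

   with Sₓₓ the visit-schedule time spread, β₁ the mean slope and Δ the
   fractional reduction (one-sided α = 0.05, power 0.80, readings at 12, 18,
   24 and 36 months).

## Worked example

```python
import numpy as np
from amytraj import (GeneratorConfig, generate_cohort, annualize,
                     RateCurveModel, shape_difference_test, linearity_test)

cfg = GeneratorConfig(seed=1, n_cases=200, control_pool_size=800)
participants, visits = generate_cohort(cfg)
ann = annualize(visits)

fit = RateCurveModel(ann).fit(target_edf=4.0)
print(fit.summary())
```

```
Penalized-spline rate curve (SUVR change/yr vs baseline SUVR)
==============================================================
group:            pooled
n observations:   1000
effective df:     4.000
penalty weight:   883.458
residual var:     0.000418821 (SUVR/yr)^2
baseline range:   [1.069, 2.409]
peak rate:        0.0535 SUVR/yr at SUVR 1.754
```

The fitted curve is the inverted U: accumulation is fastest (~0.054 SUVR/yr)
at a baseline load of ~1.75 and falls off toward both ends of the range.
Integrating it gives the sigmoid level-vs-time trajectory, and the nested
spline F tests quantify group differences and nonlinearity:

```python
traj = fit.integrate(t_max=40.0)          # starts at the 2.5th pct of baseline
sh, li = shape_difference_test(ann), linearity_test(ann)
```

```
trajectory: start 1.124, level at 10 y 1.355, at 25 y 2.086, stop: left_data_range
shape difference: F = 2.13, p = 0.06
vertical shift:   coef = 0.0007 SUVR/yr (SE 0.0018), p = 0.71
linearity:        F = 60.1, p = 1.01e-35
```

Both groups are simulated from the same accumulation law, so the shape and
shift tests are null (p = 0.06 and 0.71) while the linearity test rejects
decisively — the rate-vs-load association is genuinely curved.

The same objects power the rest of the pipeline: `association_table(ann)`
produces the 16-row clinical-association table, and
`sample_size_table(GeneratorConfig(), seed=...)` the mixed-model/jackknife
per-arm sample-size grid.  Everything is also scriptable from the shell:

```sh
amytraj run-all --seed 1 --out-dir results/run1
```

writes every intermediate artifact (cohort, matches, annualized changes,
rate-curve JSONs, group tests, trajectory, associations, sample sizes) plus
a manifest of SHA-256 hashes; rerunning with the same seed reproduces every
artifact byte for byte.

## Layout

```
src/amytraj/
  simulate.py     cohort generator (logistic accumulation, coupled decline)
  matching.py     greedy caliper matching
  annualize.py    per-year change scores
  splines.py      P-spline + natural-spline bases, edf bisection
  rates.py        RateCurveModel/Results, group tests, RK4 integration
  association.py  regression table, blocked ANOVA
  power.py        mixed models, required_n, jackknife, sample-size grid
  pipeline.py     run-all orchestration, manifest
  io.py, config.py, cli.py
docs/methods.md   modelling assumptions, defaults, limitations
```
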