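# Methods

## Model and estimation procedure

The package models the floral integrator *AGL8* as a static, linear
read-out of FT-like florigen expression.  Ordinary-differential-equation
dynamics are deliberately out of scope: with 2–4 sampling terms per
condition there is no temporal resolution to constrain rate constants, so
the regression treats each time point independently and lets the
condition structure carry the biology.

For a dataset of one (line, photoperiod), the four condition blocks
*b* = (vernalization ∈ {V, N}) × (daytime ∈ {morning, evening}) each get
their own intercept `c0[b]`, absorbing everything that regulates *AGL8*
other than the modelled FT inputs.  Regulatory coefficients stratify by
vernalization by default; the stratifier is switchable to `none` or
`daytime` so the informativeness of the vernalization split can itself be
tested (compare M1 under the three sharing schemes in the
structure-selection report).  `c0` always keeps its four block values —
only the regulatory coefficients' sharing is varied.

Every family (M1–M7) and knockout (H0–H5) is linear in its parameters;
nonlinearity enters only through the fixed regressor transform (squares,
exp, log, time gating).  Two consequences are used throughout:

* the cost is an exact quadratic in the parameters, so the weighted
  least-squares solution of the stacked block design is the global
  minimum (`wls_oracle`);
* the Nelder–Mead search — the estimation method of record — can be
  started at that solution and must agree with it, which the acceptance
  suite verifies to 1e-6 relative across all 13 specs.  Simulation
  studies with thousands of fits may use the closed form directly
  (`OptimizerConfig(method="wls")`); this is a fast path through the same
  minimum, not a different estimator.

### Cost function

```
F = Σ_b RSS_b / Σ_b'          with  RSS_b = Σ_i (y_bi − ŷ_bi)²,  Σ_b' = Σ_i σ²_bi
```

Each block is normalised by its **summed** variance, not per point: a
block's weight is one number, `1/Σσ²`.  This makes F a sum of four
scale-free block misfits, comparable across conditions with very
different expression magnitudes.  Points with σ = 0 enter the denominator
at a floor of 1e-6 (floor applied in the cost only, never when sampling);
a block whose summed variance is zero with the floor disabled is an
error.

### Resampling ensemble

Observed series are linearly interpolated in time — both the mean and the
s.d. (the "variances interpolated" reading; linear-on-sd keeps
interpolated uncertainties between their neighbours).  `n_intermediate`
interior points per interval (default 3, giving 13 points from a 4-term
series and 52 *AGL8* points per dataset) control the density; the
published analysis this design follows reports 61 and 41 total points for
its two photoperiods without stating the density rule, so the count here
is a parameter, not a target.  An ensemble (default 1000, most tests use
200) of pseudo-datasets is then drawn point-wise from Normal(mean, sd) —
untruncated, so negative draws are kept — with one global seed spawning
per-replicate substreams.

Fitting every draw yields per-parameter ensembles whose mean ± s.d. are
the reported estimates.  This is a parametric bootstrap: **the ensemble
standard deviation is the standard error of the estimate**, and recovery
checks ("truth within 3 ensemble s.e.") use it as such.  Because the FT
predictors are resampled along with *AGL8*, the design carries measurement
noise and coefficient estimates have a small errors-in-variables
attenuation bias of order (noise/signal)²; at the default noise levels it
is a fraction of one standard error and vanishes as the noise does (the
acceptance suite measures the noise ladder 0.05 → 0.01 → 0).

### Model comparison

Structures with different parameter counts are ranked by
`AICc = 2k + F_min + (2k²+2k)/(m−k−1)`, identifying `−F_min` with
`2 log L̂` of the weighted Gaussian likelihood; `m` is the number of
*AGL8* points and `m > k+1` is enforced.  The headline AICc uses the
ensemble-mean `F_min` (one value per model); per-replicate AICc spread is
reported alongside.

Knockouts share one parameter count, so they are compared directly on
their per-replicate F distributions against H0.  The default is a paired
two-sided Wilcoxon signed-rank across replicate index (the ensembles
share their resamples, and F distributions are right-skewed); Welch's
unpaired t and a paired t are available via config, and Holm correction
across the five hypotheses is off by default (raw two-level star coding
at 0.05/0.01).  The mean-F ratio vs H0 is reported as the effect size and
should always be read together with the p-value: over hundreds of shared
resamples the paired test resolves differences far below any biological
relevance (see "Calibration" below).

Block diagnostics decompose a fitted model's F into its four block
contributions (they sum to F exactly) and standardized per-point
residuals; a block is flagged when its contribution exceeds a
configurable multiple (default 2×) of the H0 fit's same-block
contribution, turning the visual "where does the knockout fail" question
into a number.

## Synthetic data generator

`synthetic_data` emulates the statistical shape of the real experiment:
4 blocks × 2–4 terms over a 14-day horizon; per-point s.d. equal to
`noise_cv · mean` (default CV 0.1, in the range of 3-replicate qRT-PCR
scatter) with an absolute floor of 0.005 expression units so near-zero
genes keep a finite σ; `flat_low` genes capped at 5% of the strongest
`flat_high` base level (the *FTa2*/*FTc2* regime); vernalization
induction as a multiplicative factor in V blocks; morning/evening
differences as an additive evening offset.  *AGL8* is always generated
from a ground-truth spec and parameter vector — never templated — so the
generating coefficients are known exactly.  Recorded means are noiseless
by default (the resampling stage supplies all stochasticity, matching the
mean ± s.d. data model); optional Gaussian observation noise on the means
is available.

Canned scenarios fix the study conditions: `Ku_like_SD` (single-driver
truth: strong rising *FTc1*, evening-elevated, others at 1%),
`Pal_like_SD` (single-driver with vernalization-dependent coefficient,
c1(V) = 2·c1(N), CV 0.05), `ku_like_LD` (joint *FTc1* + *FTa1* drive with
vernalization-stratified coefficient), `null_equal` (full-model truth,
four identical rising templates, for calibration studies), `time_gated`
(M7 truth).  What passing tests on these scenarios shows is that the
pipeline discriminates the regulatory architectures it was built to
discriminate *under its own data model*; they do not establish anything
about features the generator lacks — non-Gaussian measurement error,
correlated replicate noise, regulator–regulator dynamics, or circadian
waveforms beyond a two-point morning/evening contrast.

## Numerical choices

* Nelder–Mead: `xatol = fatol = 1e-8`, iteration budget 10⁴·k, started at
  the WLS solution; optional uniform random restarts in [−10, 10] for
  robustness checks.  Non-convergence is flagged per replicate, not fatal;
  ensemble summaries use converged replicates.
* M4 regressor is the sum of squared inputs Σ FT_i² (the squared sum is
  available behind `m4_square_of_sum`); M6 adds ε = 1e-9 inside the log
  and raises a domain error at non-positive arguments; M5 clamps the
  exponent at 700 with a warning; M7 measures time in days since the
  block's first sampling term.
* Rank-deficient designs (e.g. a constant regressor collinear with the
  block intercepts) fall back to the minimum-norm pseudo-inverse solution
  with a warning.
* CSV output uses 12 significant digits; round-trips are exact and writes
  byte-deterministic.

## Calibration and known limitations

The knockout comparison is powerful but not nominally calibrated.  Under
the `null_equal` truth — four exchangeable genes contributing equally, so
any single exclusion is compensable by rescaling — the paired test still
rejects far above the nominal rate, and Welch's unpaired alternative
essentially never rejects.  The cause is structural, not a bug: the full
model's regressor sums four resampled genes where a knockout sums three,
so the full model's design carries less relative measurement noise and
fits systematically (if minutely, mean-F ratio ≈ 1.05 at CV 0.05) better;
pairing across shared resamples resolves exactly this kind of consistent
micro-shift, while the unpaired test is blinded by the strong positive
correlation between ensembles fitted to the same draws.  The ratio of
this systematic shift to the pairing noise is invariant to the overall
noise CV, so no noise level removes it.  Practically: treat the stars as
a screen and the mean-F ratio as the decision quantity — a pattern the
two-gene scenarios illustrate, where dispensable-gene knockouts sit at
ratios ≈ 1.00 and essential-gene knockouts at 1.2–2.4.

Other limitations: linear interpolation of sparse series understates
curvature between terms; the cost assumes independent Gaussian errors
within blocks; AICc inherits the `2 log L̂ = −F` identification, which
drops block-variance constants (harmless for ranking models on one
dataset, not comparable across datasets); and the generator's defaults,
while realistic in scale, are stylised — conclusions about real lupin
lines require the original expression data, not these scenarios.
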