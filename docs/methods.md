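# Methods

This note records the models, estimators, numerical conventions and design
choices behind `tvegfuse`, and what the synthetic-data experiments do and do
not demonstrate about real transpiration products.

## Error model and estimators

All collocation estimators assume the affine error model

    x_i(t) = α_i + β_i Θ(t) + ε_i(t),   i = 1..N,

with Θ the unobserved signal, α_i/β_i additive and multiplicative biases,
and ε_i zero-mean random errors orthogonal to Θ.  Moments are always
computed over *complete* time steps (every product valid) with the
population denominator (divide by n).  The population convention is not
cosmetic: it makes the closed-form error variances and the averaged
cross-multiplied rescaled differences agree exactly on finite samples,
which the test suite asserts to 1e-10.  A `ddof` switch exposes the sample
convention for users who prefer it.

**Triple collocation** (`tc_error_variances`) assumes all error pairs
uncorrelated and returns
`σ²_εX = σ²_X − σ_XY σ_XZ / σ_YZ` (cyclic), with the subtracted term
reported as the sensitivity `β²_X σ²_Θ`.  Rescaling (`tc_rescale`) maps
product Y into X's data space via `β_Y^X = σ_XZ / σ_YZ`.

**EIVD** (`eivd_estimate`) relaxes the zero-ECC assumption for one declared
pair by using each product's lag-1 shifted series as an instrument.  Errors
being serially white, the lag-1 autocovariance of a product is
`L_ii = β_i² C_Θ(1)`, so `√(L_ii / L_jj)` is a consistent estimate of
`β_i / β_j` that is immune to error covariance.  These dynamic-range ratios
scale the cross-covariances into ten moment equations in eight unknowns
(three sensitivities, one cross-sensitivity, three error variances, one
error covariance), solved by ordinary least squares.  The design matrix is
fixed and full-rank; a reciprocal-condition guard (< 1e-10) flags degenerate
pixels anyway.  Preconditions: the declared pair is mapped internally to
positions (X, Y); all three lag-1 autocorrelations must exceed 3/√n (under
a serially white series the sample lag-1 autocorrelation has standard
deviation ≈ 1/√n, so this is a one-sided 3-σ significance screen).  A
white-noise signal therefore fails the precondition rather than producing a
spurious estimate.

**Extended collocation** (`ec_quadruplet_estimate`, N = 4) accepts a set of
declared non-zero ECC pairs, first validated combinatorially: every product
must belong to at least one triplet whose three pairs are all declared
zero, otherwise the moment system is rank-deficient and the call is
rejected with a diagnostic before any computation.  The estimator stacks,
for every admissible triplet, the sensitivity identities
`S_m = σ_mk σ_ml / σ_kl` and cross-term identities
`C_ab = σ_ak σ_bl / σ_kl`, plus the variance/covariance decompositions, and
solves by least squares.  Using *all* admissible triplets (rather than one
arbitrary choice) averages sampling noise at no extra cost.

Negative variance estimates and |ECC| > 1 are **flagged invalid, never
clipped**; downstream code must consult the validity masks.  This keeps the
estimator honest and pushes repair policy into the merging stage where it
can be recorded.

Open choices resolved here: estimation operates on raw series (no
climatology removal) — the lag-1 autocovariance alone removes the mean;
"lag-1" means one step of the native time axis (8 days for the gridded
product); the minimum sample screen defaults to 100 complete steps per
pixel.

## Merging

Weights minimise the merged error variance subject to summing to one:
`W = Σ⁻¹1/(1ᵀΣ⁻¹1)`, merged variance `(1ᵀΣ⁻¹1)⁻¹`.  Closed forms for
N = 2 (independent errors) and N = 3 with one correlated pair match the
matrix solution to machine precision (asserted).

Because merging happens *after* rescaling all products into a reference
data space, the covariance fed to the weight solver must live in that space
too: rescaling multiplies product i's error by `β_ref / β_i`, estimated as
`√(sens_ref / sens_i)` from the collocation sensitivities
(`rescale_covariance`).  Without this step the predicted merged variance is
in mixed units and does not match the measured MSE; with it, the empirical
merged MSE tracks the prediction within a few percent in the Monte-Carlo
experiments.

The reference data space defaults to the product with the largest estimated
sensitivity (the one whose variance is most signal); it is configurable.
Weights are static over the record.  At merge time, steps with missing
products renormalise the weights over the available products (configurable
strict mode drops the step).  Repair policy for invalid inputs or
out-of-range weights: drop flagged products, recompute on the valid subset,
then fall back to equal weights; every repair is recorded in the weight
vector's provenance fields and counted in the pipeline report.

## uWUE partitioning

`uWUE = GPP·√VPD / ET` is treated as proportional through the origin, so
both regressions are zero-intercept: the ratio definition implies
proportionality, and an intercept would absorb the signal the slope is
meant to capture.  The annual potential value uses a 95th-percentile
through-origin quantile regression, solved exactly: for a single
non-negative regressor the pinball-loss minimiser is the weighted
q-quantile of the ratios `y_i/x_i` with weights `x_i` (deterministic,
closed form; cross-checked against iterative quantile-regression fits in
the tests).  The apparent value is a centred 8-day moving-window
least-squares slope `Σxy/Σx²` requiring at least 8 valid points.  Days with
rain above 0.1 mm plus the following day, and quality-flagged records, are
excluded through a validity mask before any fitting.  `T/ET = uWUE_a /
uWUE_p` is clipped into [0, 1] with clip counts reported, since envelope
noise can push the ratio slightly above one.  Externally computed
transpiration series (e.g. from optimisation- or learning-based
partitioning methods) enter through `benchmark_mean`, which averages per
step over whichever methods have a value there.

## Evaluation

RB is signed, `(mean_est − mean_ref)/mean_ref` (the sign convention is in
the output metadata).  "Modified KGE" is the 2012 variant whose variability
term is the ratio of coefficients of variation; the 2009 variability-ratio
form is behind a flag.  Group tables report mean ± population sd
(configurable to sample sd).  The Mann–Kendall test uses the exact
permutation distribution of S for n ≤ 8 — the tie-corrected,
continuity-corrected normal approximation can deviate from the exact
two-sided p by more than 0.01 that small — and the normal approximation
above.  Theil–Sen slopes are medians of pairwise slopes.

## Synthetic data: what it emulates and what it does not

The truth signal is mean + sinusoidal seasonal cycle + stationary AR(1)
anomalies.  Nothing in the method chain depends on this specific form; it
is the minimal model with the non-zero lag-1 autocovariance the
instrumental variables require.  Errors are multivariate normal,
serially white, with a prescribed covariance matrix — the error model
specifies only the first two moments, and normality is the minimal
completion.  Defaults sit in the regime reported for real transpiration
products: error variances (0.36, 0.29, 0.13) mm² day⁻², one correlated
pair with covariance 0.10 (ECC ≈ 0.31), product gains (1.0, 0.8, 1.2).

Deliberately *not* emulated: spatial autocorrelation between pixels (pixels
are independent realizations), retrieval artifacts specific to any real
product, non-stationary or heteroscedastic errors, and serially correlated
errors.  Passing tests therefore demonstrate estimator correctness under
the stated assumptions, not robustness to their violation; distributional
sensitivity of the instrumental-variable estimator is untested.

Site records are built so that `GPP·√VPD = uWUE_p · T` holds exactly before
noise, with `T = (T/ET)·ET` from a prescribed ratio schedule.  Default GPP
noise is multiplicative lognormal with cv = 0.02.  The 95th-percentile
envelope regression has an upward bias of order `z_q · cv` when the
envelope days carry multiplicative noise; cv = 0.02 keeps the potential
uWUE recoverable to ~2%, which is the precision the recovery experiments
target.  Larger noise degrades uWUE_p (and hence the ratio) gracefully, not
catastrophically.

## Problem sizes and numerics

The Monte-Carlo experiments use 200 replicates at 5×10⁴ steps for
estimator recovery (relative biases < 1% in practice), 200 replicates at
5×10³ steps for merging optimality, and a 10×10 pixel, 500-step grid for
the end-to-end pipeline — sizes at which sampling error is well below the
effects being measured while the whole suite runs in seconds.  Linear
systems go through `numpy.linalg.lstsq`/`solve` with explicit conditioning
guards rather than matrix inversion.  netCDF output prefers the installed
engine and falls back to the scipy (netCDF-3) backend; merged files follow
the `Merged.Tveg.<year>.nc` convention with `lat` ascending, `lon` in
[−180, 180), integer `day` of year, and `Ec` in mm day⁻¹.  An 8-day-native
and a daily output mode exist; the daily mode repeats each 8-day value onto
its constituent days.

## Known limitations

- One declared ECC pair at merge time (estimation supports more via the
  quadruplet path; the merging API accepts any full covariance matrix).
- Static weights; no seasonally stratified or time-varying weighting.
- No bootstrap confidence intervals on collocation estimates.
- Regridding is bilinear/nearest interpolation, not geostatistical.
- The pixel loop is serial; it is embarrassingly parallel but no
  distributed runtime is bundled.
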