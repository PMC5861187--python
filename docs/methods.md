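# Methods

This note records the models, parameter choices and numerical decisions
behind `psyconn`, and what the synthetic validation does and does not show
about real data.

## Synthetic cohort model

**Scores.**  Each psychometric parameter is drawn i.i.d. across subjects
from a Gaussian truncated to the questionnaire scale (default [0, 130]),
parameterized by a per-parameter mean and SD (defaults 58.38 and 10.40, a
representative battery).  Only marginal moments are modeled; parameters
are generated independently unless a correlation structure is supplied,
because the joint distribution of real batteries is not identified by
published summary tables.  Missingness is block-structured: a subject
either has a whole battery or none of it, emulating multi-day acquisition
(e.g. 153/134/123 subjects across three batteries).

**Gray-matter maps.**  A subject's map is a constant baseline plus, for
each planted focus, a Gaussian bump (unit peak, width equal to the assumed
8-mm FWHM smoothing) scaled by `β_vbm · (score − mean)`, plus a smoothed
Gaussian noise field rescaled to a target voxel SD (default 0.05 density
units).  The value at the focus voxel is therefore exactly
`baseline + β_vbm·(score − mean) + noise`.  Maps are clipped at zero
(density is non-negative); TBV is the map sum times the voxel volume.
Segmentation, registration and modulation of real T1 images are out of
scope — the generator emits already-normalized, already-smoothed maps,
matching the pipeline position of the morphometry stage.

**Time series.**  Each subject's T × R series (default T = 480, TR = 1 s)
is i.i.d. multivariate normal with unit variances and correlation r0
(default 0.1) off-diagonal, except on planted edges where the population
correlation is `clip(r0 + β_edge·z_score, −0.95, 0.95)`.  Matrices made
indefinite by planted edges are projected to the nearest positive-definite
correlation (eigenvalue floor 1e-6, diagonal renormalized).  Confounds are
Friston-24-shaped: six AR(1) "motion" series (φ = 0.95), their one-sample
lags, and the squares of both.  No hemodynamic response, physiological
noise spectra or scanner drift are modeled.

**Effect-size calibration.**  The quantity that drives downstream power is
the correlation between the score and the *observed* edge weight.  The
observed weight is the planted population value plus sampling noise whose
variance depends on how much information survives preprocessing, so the
generator measures an effective sample count empirically: pairs of
independent series are pushed through the actual confound regression and
bandpass filter, and the variance of their sample correlation is inverted
(`N_eff = 1/var + 3`; about 47 for T = 480 with the default chain — the
24 smooth confound regressors overlap the 0.01–0.1 Hz passband and cost
roughly half the ideal-bandwidth samples).  `edge_effect_for_target_
correlation` then inverts `ρ = β/√(β² + 1/(N_eff − 3))` for β.  With a
target ρ = 0.4 the realized edge–score correlation measures ≈ 0.40 at
n = 150.

## Morphometry

The voxelwise fit is `density ~ 1 + score + TBV`, slope t with n − 3
degrees of freedom, two-sided p.  Zero-residual voxels (relative residual
sum of squares ≤ 1e-12) are flagged as perfect fits (t = ±∞, p = 0).

Small-volume FWE uses a within-parcel permutation max-|t| test (default
1,000 permutations) rather than random-field theory: scores are permuted
across subjects, the within-parcel maximum |t| forms the null, and a voxel
survives iff its uncorrected p ≤ 0.001 *and* its |t| exceeds the 95th
percentile of that null.  This is a deliberate contract difference from
SPM-style voxel-level FWE — distribution-free, and exact under
exchangeability — while keeping the same per-gyrus correction structure.
The conjunction (AND) reading of the two thresholds is adopted.  Tests
confirm familywise false-positive control at or below the nominal level.

ROI definition: one ROI per significant (parameter, parcel) mask, a sphere
of radius diameter/2 (default 5-mm diameter) at the world coordinate of
the max-|t| voxel.  Peak ties break to the smallest linear voxel index in
x-fastest scan order — deterministic and grid-stable.  "Overlap" in the
dedup pass is read geometrically as sphere intersection: an ROI is dropped
iff its center is closer than the sum of radii to an already-retained ROI,
in a single forward pass over the parameter-ordered list, so the first
occurrence always wins and the pass is idempotent.  Correlation is treated
sign-agnostically throughout (two-sided tests, |t| peaks).

## Connectivity

Stage order is fixed: confound regression, bandpass, correlation — the
listed order of the reference preprocessing chain.  The filter is a
4th-order Butterworth run forward and backward (zero phase), so filter
delay cannot distort inter-regional correlations; probe-tone tests show
≥ 99% amplitude at 0.05 Hz and ≤ 1% at 0.005/0.2 Hz.  Correlations are
used raw (no Fisher z) downstream, since the edge regression contract is
on the correlation coefficients themselves.  CSF-style artifact regressors
can be appended to the confound matrix by the caller; there is no
dedicated stage.

## Network inference

Edge-wise simple regression `r_edge ~ 1 + score` (t with n_eff − 2 df,
missing-score subjects dropped per parameter).  Components are extracted
from the graph of edges with two-sided p below the primary threshold
(default 0.005), mixing positive and negative slopes in one graph.  The
component statistic is extent (edge count), not intensity.  The
permutation scheme permutes the score vector across subjects — the same
null as shuffling subject labels on the correlation matrices, at a
fraction of the cost — and the add-one convention bounds attainable
p-values below by 1/(n_perm + 1).  Default n_perm is 5,000; simulation
tests and the acceptance script use 1,000 for tractability.

Edge-count targeting evaluates the loosest threshold (0.005) first: if
nothing is FWE-significant the parameter yields no network; if the largest
significant component is already at or below the target (15 edges) it is
returned unchanged; otherwise a log-scale bisection over
[1e-6, 0.005] minimizes |size − target| with ties toward the stricter
threshold.  The same seeded permutation stream is reused at every
threshold, making sizes monotone in the threshold and the search
deterministic.

A note on calibration: with 30 ROIs and a 0.005 primary threshold the null
supra-threshold graph holds only ~2 edges, so the max-component statistic
is heavily tied on small integers and the permutation test runs
conservative — the measured null familywise rate is ~0.02–0.03 against
the nominal 0.05.  This is inherent to discrete extent statistics at small
R, not an implementation artifact; at atlas scale (R > 100) the statistic
has far more resolution.

## Classification

Discretization maps the observed score range onto classes 1..8 by
`⌈8·(x − min)/(max − min)⌉`, clamped into [1, 8]: the round-up rule as
stated, with two documented edge readings — x = min (which ceils to 0) is
clamped to class 1, and exact-integer products keep their value (there is
no digit to round up).  Products are rounded to 9 decimals before the
ceil so float fuzz cannot flip an exactly-integer product across a class
boundary.  Training min/max are stored and reused for held-out subjects
(out-of-range scores clamp with a warning).

One binary RBF-SVM per observed class (libsvm via scikit-learn; classes
absent from a training fold simply contribute no classifier), prediction
by maximal decision value with ties to the lowest class.  Features are
standardized per column with training-fold mean/SD inside every
cross-validation fold — the RBF grid assumes comparable feature scales —
and the scaler is stored with the model.  Grid search maximizes LOOCV
accuracy over the dyadic grids, scanning in ascending (C, γ) order with
strict improvement required, so ties break toward smaller C then smaller
γ and the search is fully deterministic.  The paper-style flat scheme
(model selection on the same LOOCV loop that is reported) is the default
contract; its optimistic bias is acknowledged and the held-out apply flow
is the unbiased check.

The corrected chance level is the binomial (1 − α) quantile:
`100·k/n` with k the smallest correct-count whose cumulative probability
under Binomial(n, 1/8) reaches 0.95 — 26/150 = 17.33% at n = 150,
11/57 = 19.30% at n = 57.  Significance against chance is an exact
one-sided binomial test of the correct-count (primary); a one-sample
t-test on the 0/1 correctness vector is available as a secondary mode for
comparability with t-test-based reporting, which is ill-posed for a single
aggregate accuracy.

## Pipeline and problem sizes

A single global seed expands into per-stage child seeds via
`SeedSequence(seed, spawn_key=(stage,))`, so stages can be re-run in
isolation.  In the simulated training flow the connectivity stage operates
on the generator's ROI-indexed time series while morphometry demonstrates
structural discovery on the same cohort's maps; the manifest records both,
and its consistency invariant (classifiers ⊆ networks) is enforced.

Monte-Carlo suites run at desk scale by design: 150 subjects, 30 ROIs,
480 samples, 1,000 permutations, 8³ simulation grids with 8 parcels, and
reduced SVM grids (C ∈ {2⁰, 2⁴}, γ ∈ {2⁻⁶, 2⁻³, 2⁻¹}) in simulation
loops; the library defaults remain the full dyadic grids and 5,000
permutations.  The NBS recovery validation plants edges at edge–score
correlation 0.4.  The end-to-end validation's "strong signal" condition is
a power calculation: exact 8-class matching at n = 57 carries binomial
noise of about 6 percentage points plus class-boundary alignment luck, so
the planted correlation (0.75) is set where the expected held-out accuracy
(~40%) clears the 19.3% corrected chance by well over two SDs — at weaker
signal (0.5, held-out accuracy ~28%) individual cohorts cross the bound by
chance even though the classifier's confusion stays concentrated near the
diagonal.

## Limitations

Passing the synthetic suite shows the statistics are implemented correctly
and powered as designed under the generator's assumptions — i.i.d.
Gaussian samples, stationary correlation, block missingness, linear
score–effect coupling.  It does not certify behavior under real-data
violations: temporal autocorrelation, motion artifacts correlated with
scores, non-Gaussian score distributions, atlas misregistration, or
between-site effects.  The morphometry FWE correction is permutation-based
and will differ numerically from random-field-theory corrections on the
same data.  Real headline counts from cohort studies (numbers of ROIs,
networks and classifiers) depend on private data and are reproduced here
structurally, not numerically.
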