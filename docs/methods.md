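# Methods

`salnet` re-implements, as a tested pipeline, an analysis linking past-year
violence exposure, personalized salience-network properties, and depression
in an adolescent cohort, with sex as the moderator of every association.
This note records the models, the generator that stands in for the
(undeposited) cohort data, the numerical choices, and what the tests do and
do not establish.

## The analysis model

For subject *i*, let Y\_i be depression severity (a sum of 11 items rated
0–3), X1\_i a female indicator, X2\_i the past-year violence-exposure count
(sum over 7 event types), and M1\_i / M2\_i the two salience-network
metrics: **expansion** (the fraction of all cortical vertices classified as
significant salience-network members) and **connectivity** (the mean
Pearson correlation of the nuisance-regressed BOLD time series over all
unordered pairs of member vertices). Eight fixed-effects OLS models are
fit, each with IID Gaussian errors:

```
(1)  X2 = b0 + b1 X1
(2)  Y  = b0 + b1 X1 + b2 X2 + b3 X1·X2
(3)  M1 = b0 + b1 X1 + b2 X2 + b3 X1·X2
(4)  M2 = b0 + b1 X1 + b2 X2 + b3 X1·X2
(5)  Y  = b0 + b1 X1 + b4 M1 + b5 X1·M1
(6)  Y  = b0 + b1 X1 + b4 M2 + b5 X1·M2
(7)  Y  = b0 + b1 X1 + b2 X2 + b4 M1 + b5 X1·M1
(8)  Y  = b0 + b1 X1 + b2 X2 + b4 M2 + b5 X1·M2
```

All non-indicator variables are z-scored on the analysis sample
(mean 0, variance 1, ddof = 1); indicator columns (sex, Black, White,
Hispanic) are left untouched; interaction columns are products of the
*scaled* columns (scale-then-multiply — the ordering was an open choice and
is fixed here). Each model runs under four covariate sets: none; seven
demographic covariates (age, Black, White, Hispanic, BMI percentile,
puberty category, income-to-poverty ratio); the model's dependent variable
measured two years earlier ("lagged"); and both — 32 fits in total, with
two-sided t-based p-values and no multiple-testing correction (the report
carries the count of tests performed). Puberty category enters as a
numeric, z-scored covariate. Mediation is intentionally out of scope.

Missing time-1 network metrics are singly imputed by OLS on time-1-only
predictors (sex, race/ethnicity indicators, income-to-poverty ratio,
time-1 depression and violence) fit among complete cases; time-2 columns
are never used as predictors, and imputation flags are recorded.

Two decompositions accompany the battery: sex-stratified Pearson
correlations with t = r·sqrt(n−2)/sqrt(1−r²) on n−2 df, and a two-group
one-way ANOVA of violence counts by sex computed from group summary
statistics (between-group mean square over pooled within-group mean
square, df (1, n1+n2−2)).

## Network metrics

**Preprocessing.** Each vertices × time run is residualized in a single
joint least-squares projection against: six motion parameters and the
global signal (the across-vertex mean), their backward-difference
derivatives (leading 0), squares, and squared derivatives (28 columns); a
discrete-cosine high-pass basis — basis j is cos(πj(t+½)/T), unit
normalized, with floor(2·T·TR·0.01 Hz) bases (12 at the 1110-frame,
555 ms acquisition); and one one-hot spike regressor per DVARS-flagged
frame. A constant is always part of the projection even though it is not
counted among the design columns; this guarantees residual variance never
exceeds input variance and makes residuals orthogonal to the raw (not just
demeaned) columns. White-matter and CSF signals are excluded by design
(they are nearly collinear with the global signal). Frames are flagged by
a dual-cutoff DVARS rule: the squared frame-to-frame RMS change must
exceed its robust null center (the median) by more than 5% of the mean
temporal variance (the "practical" cutoff), *and* fall below α = 0.05
Bonferroni-corrected across the T−1 differences under a moment-matched
chi-square null (center from the median, spread from the IQR/1.349).
The cutoff values are configurable; flagged frames are spike-regressed,
not deleted, so the later half-split keeps its frame arithmetic.
Vertices with post-regression variance below 1e−10 mark the subject
metric-invalid (threshold configurable).

**Parcel-seeded dual regression.** Stage 1 averages the time series over
the vertices of each of the K = 17 parcels of a hard parcellation (the
salience / ventral-attention B slot is network 8); stage 2 regresses every
vertex's time series on the K parcel courses jointly with an intercept,
giving a V × K engagement map and vertex-wise OLS sampling variances.
Because global-signal regression forces the across-vertex residual mean to
zero, the parcel-size-weighted sum of the K courses vanishes and the
stage-2 design is rank-deficient by exactly one; the fit therefore uses
the truncated-SVD minimum-norm solution (relative singular-value cutoff
1e−10), which is deterministic and stable. Duplicated parcel courses
still raise an error naming the parcels. Engagement maps are
variance-normalized per network (unit across-vertex SD) before both prior
estimation and shrinkage, since dual regression leaves each network's
scale indeterminate.

**Pseudo test-retest prior.** Each selected session (one per subject,
chosen by a seeded draw when a subject has two) is split down the middle;
each half yields an engagement map. With half-maps (a, b) per session,
per (vertex, network): the prior mean is the grand mean of (a+b)/2; the
half-map noise variance is w = mean of (a−b)²/2; and the between-subject
variance is the sample variance of (a+b)/2 minus w/2, floored at zero
(the floored fraction is logged). This method-of-moments decomposition is
a declared reconstruction of the test-retest variance separation used by
template-based individual-mapping methods; it is unbiased in simulation
and is validated against its closed-form identity in the tests.

**Empirical-Bayes shrinkage and inference.** Per vertex and network the
posterior is the conjugate-normal precision-weighted average of the prior
mean (precision 1/between-variance) and the subject's raw estimate
(precision 1/sampling-variance); the shrinkage weight therefore adapts
automatically to the data quality. Degenerate cases: zero between-variance
returns the prior mean with a configurable standard-error floor (1e−6);
infinite sampling variance (a dropped network) returns the prior; an
infinite prior variance returns the raw estimate. Membership in the
salience network is a one-sided normal test of positive engagement at
α = 0.01 Bonferroni-corrected across **all** V vertices (20484 at full
resolution), with negative engagements excluded regardless of magnitude;
a two-sided-then-drop-negatives variant sits behind a flag. The posterior
standard error is treated as known (normal reference), justified by the
long acquisitions. Expansion is the member fraction of all vertices;
connectivity is the mean pairwise member correlation computed on the
full-length nuisance-regressed session (not the pseudo-halves) via the
closed form sum‖Σz‖² identity, which the tests check against a naive
double loop.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes; it
is the study condition, not a tuning dial.

* **Atlas**: K index-contiguous vertex blocks with Dirichlet-drawn sizes —
  no surface geometry, since every metric depends only on labels.
* **Subject maps**: vertex-wise Normal draws around a population truth
  (default: mean 1 inside a network's parcel, 0 outside; between-subject
  SD 0.5 inside, 0.05 outside). The inside-SD default is chosen so that
  individual network borders genuinely differ across subjects, as they do
  in real cohorts; with much smaller values every subject's membership
  mask collapses onto the parcel boundary and expansion degenerates to a
  few quantized values.
* **BOLD**: maps × time-courses plus structured nuisance. Network courses
  are AR(1)-smoothed Gaussian noise, QR-orthogonalized and unit-variance
  (the temporal model was unspecified; decorrelation makes small-T
  recovery exact). Nuisance: slow polynomial/cosine drift with random
  vertex loadings, AR-random-walk motion with linear vertex coupling and a
  matching 6-column motion table, rare global spikes, and white noise.
  All magnitudes zero reproduces the exact signal product.
* **Phenotypes**: sex ~ Bernoulli(141/220 female); violence counts are
  sex-specific negative binomials with means (1.16, 2.95) and the size
  parameters r = μ²/(σ²−μ) = (0.302, 0.386) implied by the cohort's
  printed SDs (2.37, 5.05) — the dispersion was otherwise a free choice.
  Mediators and outcome follow the battery's own equations on the
  standardized scale (population-standardized violence), with generating
  coefficients defaulting to the cohort's reported standardized effects
  (e.g. sex-by-violence interaction 0.337 on depression, female indicator
  0.399) and null exposure effects on the network metrics. The depression
  residual SD defaults to sqrt(1 − Var(linear part)), computed in closed
  form from the negative-binomial mixture moments, so the standardized
  outcome has unit population variance and the generating coefficients
  are directly recoverable by the standardized fit. Continuous phenotypes
  are affine maps with the cohort's observed moments (depression
  8.8 ± 5.29); depression stays **continuous** by default because
  rounding/clipping to the 0–33 survey scale would bias linear-model
  recovery — `discretize=True` produces survey-scale integers. Time-1
  variants are generated with correlation 0.5 to their time-2 latents.

What the generator does **not** emulate: cortical geometry and spatial
autocorrelation, hemodynamics, physiological noise, non-Gaussian BOLD
artifacts, item-level survey structure, and any genuine causal pathway
from simulated BOLD to simulated phenotypes (the pipeline's metric columns
replace the generator's in the end-to-end run). Passing tests therefore
demonstrate the estimators' correctness and calibration under the assumed
structure, not robustness to real-data violations of it.

## Problem sizes and numerical choices

Desk-scale defaults are V = 2000 vertices, T = 400 frames, n = 40
subjects, two sessions each; the full-scale geometry (V = 20484,
T = 1110, TR = 0.555 s) is available by config. Monte-Carlo suites use
300 replicates for coefficient recovery (tolerance 3 Monte-Carlo SEs) and
1000 null replicates for type-I calibration; the prior estimator is
validated on 500 simulated sessions. A small O(1/n) residual bias from
sample-standardizing the heavily skewed counts (measured at about −0.004
on the interaction coefficient at n = 220) sits well inside those
tolerances. All randomness flows from one integer seed through spawned
generators; identical configs are bit-reproducible. Vertex indexing is
0-based in memory and 1-based on disk; the synthetic flat-binary BOLD
dialect is little-endian float64, row-major vertices × time, with a JSON
sidecar (V, T, TR, seed).

## Known limitations

* The prior's variance decomposition reconstructs the test-retest
  separation from half-session splits only; it does not model spatial
  covariance between vertices, and the half-length noise correction
  assumes the two halves are exchangeable.
* Connectivity uses a binary membership mask; a posterior-weighted variant
  is not implemented.
* The battery's "lagged" covariate for the violence model uses time-1
  violence counts; real cohort analyses may not have collected that
  column, in which case that one fit is dropped by passing a table
  without it.
* Single (not multiple) imputation of time-1 metrics understates
  imputation uncertainty in downstream standard errors.
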