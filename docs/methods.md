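# Methods

## The model and its assumptions

`vectorenm` estimates climatic suitability with a presence–background
maximum-entropy model. The accessible area M — every grid cell whose
center lies within a buffer (default 200 km, haversine) of a thinned
occurrence record — defines the background; the model is the Gibbs
distribution over background cells whose feature expectations match the
presence sample, subject to per-feature L1 penalties. This carries the
usual assumptions of correlative niche modelling: occurrences sample
the environment proportionally to suitability within M, the climate
variables capture the physiologically relevant gradients, and the
species–environment relationship is transferable to the projection
extent (the MOP surface quantifies where that last assumption is
strained).

Feature classes are the standard l/q/p/t/h basis: linear, quadratic,
pairwise products, step indicators, and forward/reverse hinges. Knots
for t/h sit at the deciles of each variable on the training background
(9 interior knots by default). All raw features are affinely rescaled
to [0, 1] using background min/max; source variables are clamped to
their training range before prediction on transfer stacks, with the
MOP strict-extrapolation mask carrying the associated risk information.

Per-feature penalties are `β_j = RM · β_class(n) · sd_j / √n`, with
`β_class(n)` the published class-specific defaults (interpolated in the
presence sample size n for linear/quadratic/product, 0.5 for hinge,
interpolated 2→1 for threshold), `sd_j` the presence-sample standard
deviation of the feature (floored at 1e-3), and RM the user-facing
regularization multiplier. Output scales: `raw` is the Gibbs
probability normalized over the training background (sums to 1 there,
used for AICc); `cloglog`, the default for mapping, is
`1 − exp(−e^H · raw)` with H the entropy of the fitted background
distribution.

## Optimization

The penalized objective is convex; it is minimized by proximal gradient
descent (iterative soft-thresholding) with a backtracking line search,
which makes the recorded objective non-increasing by construction.
Convergence is declared when the objective improves by less than `tol`
(default 1e-6) in one step; hitting `max_iter` (default 500) instead
produces a warning and a flagged result, never a silent success. The
log-partition term uses `logsumexp`. This reaches the same optimum
family as the classic sequential-update algorithm; weight-for-weight
compatibility with the legacy java implementation is a non-goal.

## Candidate evaluation and selection

Candidates form a grid of variable sets × feature-class subsets × RM
values (the canonical RM grid is 0.1, 0.3, 0.5, 0.7, 1, 2, 3, 5, 7,
10; all 31 non-empty class subsets are available and the configured
run may restrict both axes). Three stages:

1. **Significance — partial ROC.** The model curve plots sensitivity of
   the evaluation points against the proportion of cells predicted
   suitable, across thresholds. The partial AUC restricted to
   sensitivity ≥ 1 − E (E = 0.05) is divided by the partial AUC of the
   random-expectation diagonal over the same area range; bootstrap
   iterations (default 500) resample ⌈0.5 n⌉ evaluation points with
   replacement, and p is the fraction of iterations with ratio ≤ 1.
   *Design choice:* the integration region is fixed by the full
   evaluation sample rather than re-derived inside each bootstrap
   iteration. Re-deriving it per iteration selects on the resampled
   curve's own noise and inflates the test's type-I error several-fold;
   with the fixed region the measured rejection rate under a null of
   uninformative points is ≈ 0.05 at n = 145 (see the acceptance
   suite). A constant prediction surface makes the ratio undefined and
   is reported as ratio 1, p 1 with a warning.
2. **Performance — omission.** The binarization threshold is the
   `(⌊E·n⌋+1)`-th smallest calibration-occurrence suitability (the
   largest observed value keeping calibration omission ≤ E); the
   omission rate of evaluation points at that threshold must be ≤ E.
3. **Complexity — AICc.** `AICc = 2k − 2lnL + 2k(k+1)/(n−k−1)` with
   lnL the raw-scale log-likelihood of the calibration points, n the
   calibration presence count, and k the number of weights larger than
   1e-8 in magnitude; k ≥ n − 1 reports +∞ with a flag. Ties are broken
   by smaller k, then fewer variables, then candidate id.

If no significant candidate meets the omission criterion the report
falls back to the minimum-omission candidates and is marked
`relaxed`. Binarization uses calibration (not evaluation) occurrence
suitabilities, and the present-day threshold is reused for every
future projection so binary maps are comparable across time; both
choices are configurable interpretations of a protocol that does not
pin them down.

## Transfer, ensembles, exposure

The selected configuration is refitted on bootstrap resamples (default
10) of the calibration occurrences; the final map is the per-cell
median across replicates, computed for the present baseline and every
(GCM, RCP, period) stack. Ensemble agreement counts suitable votes per
cell; the cutoff is ⌈0.6 G⌉ (12 of 20). Change classes: present-suitable
cells split into stable-strong (votes ≥ cutoff) and weakening;
present-unsuitable cells into gain-strong, gain-weak (0 < votes <
cutoff) and unsuitable. MOP standardizes each variable by its
calibration range, takes per projection cell the mean distance to the
nearest 10% (default) of up to 5000 sampled calibration cells, and maps
it to similarity `1 − d/d_max`; strict extrapolation flags any variable
outside the calibration min–max.

The exposure statistic is deliberately simple: per (region,
cattle-category) stratum, `100 × gain cells / present-suitable cells`,
with gain = gain-strong by default (optionally including gain-weak).
The denominator is the *present* suitable area, so values can exceed
100% where a stratum's range is projected to grow beyond its current
size; "both"-scenario rows use the union of the per-scenario gain
cells, which is why they can exceed either scenario alone. Strata with
no present-suitable cells are reported blank (undefined), not zero.
Cattle categories use breakpoints 0, 1, 5, 10, 20, 50, 100 head per
10 km² with `[low, high)` intervals and a final open `[100, ∞)` class.
Cell counts are unweighted by default; cos(latitude) area weighting is
a config option left off because the category tables are count-based.

## Synthetic data: what it does and does not emulate

The generator produces the statistical structure the analysis assumes,
not climate physics:

- **Environmental layers** are Gaussian random fields (kernel-smoothed
  white noise, default σ = 3 cells) whose cross-layer sample
  correlation reproduces a prescribed PSD matrix essentially exactly
  (the smoothed fields are orthonormalized before mixing with the
  matrix factor). Default: 7 layers, pairwise r = 0.3, echoing a
  bioclim + relative-humidity candidate set.
- **Futures** are baseline + per-(RCP, period) additive shift +
  per-(GCM, layer) constant offset (default sd 0.3, 20 pseudo-GCMs, two
  RCPs × two periods), giving an ensemble whose mean anomaly equals the
  prescribed shift.
- **Truth suitability** is cloglog of a linear + quadratic predictor on
  a subset of layers (default: first five, weights 0.8 and −0.5), so
  the generating process lies inside the fitted lq family and
  parameter/rank recovery is a meaningful test.
- **Occurrences** are multinomial draws of cells proportional to truth
  suitability, placed at cell centers — no sampling bias, no
  observation error, no sub-cell jitter.
- **Cattle** is a lognormal field (right-skewed, as censuses are);
  **regions** are contiguous vertical bands.

Passing tests on these data show the pipeline's operations are correct
and statistically calibrated under its own assumptions. They do not
show robustness to the pathologies of real data — spatially biased
sampling, label noise, non-stationary responses, correlation structure
that differs between calibration and transfer regions.

## Problem sizes and numerical details

The test and acceptance workloads use a 60 × 60 cell grid at 0.2°,
300 presences, 500 partial-ROC iterations, and a 5-set candidate grid
for recovery experiments (20 replicates); the demo pipeline uses a
50 × 50 grid, 250 occurrences, 5 pseudo-GCMs and 5 bootstrap
replicates. These sizes keep every example reproducible in seconds on
one CPU while leaving all algorithmic paths identical to full-scale
runs; every size is a config knob.

Other numerical choices: haversine distances on a sphere of radius
6371.0088 km (never a fixed degrees-to-km factor); thinning by
randomized-restart greedy removal (closest violating pair, drop the
member with more neighbors within d, ties at random; default 100
restarts, largest surviving set wins) with the ≥ d certificate
verifiable in O(n²); splits use round-half-up for the calibration
count; the collinearity filter drops, among violating layers, the one
with the largest mean |r| to the remaining layers, ties to the
lexicographically later name; delta downscaling interpolates additive
anomalies bilinearly at fine-cell centers (edge half-cells take the
nearest edge value) with optional clipping, e.g. to [0, 100] for
relative humidity; constant layers are removed from filtering with a
warning; zero-variance features are dropped to 0 after scaling.
Single global seeds expand into per-stage seeds by a fixed counter
scheme so stages rerun identically in isolation.

## Known limitations

- The candidate grid is exposed in full but the package takes no
  position on which subset of the 31 feature-class combinations a
  given study should run; published candidate counts are not always
  derivable from the stated grid axes.
- Percent "variable contribution" heuristics tied to sequential-update
  solvers are not reproduced; weight inspection and the candidate
  table are the supported diagnostics.
- No reprojection: all rasters must share one geographic grid.
- MOP is reported as a single multivariate surface; per-variable
  decomposition is out of scope.
- The exposure table's percent-modification definition is an explicit
  interpretation (gains relative to present-suitable counts, "both" as
  union); alternatives are configurable but not default.
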