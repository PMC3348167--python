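# Methods

## The problem

Normal aging shrinks gray matter (GM), but not uniformly: some regions lose
volume directly with age, while others change only subtly yet co-fluctuate
with the directly affected regions. Voxelwise univariate tests (the standard
VBM approach) find the first kind and miss the second. `sparsevbm`
implements a multivariate pattern-analysis pipeline that treats the
young/old label vector as a sparse linear combination of voxel columns and
uses L1-minimisation to rank voxels jointly, so that covarying structure can
be rewarded even when marginal effects are weak.

## The model and the selection procedure

Given a cohort of N subjects with smoothed GM density maps flattened to an
N x V matrix A under an analysis mask, and labels y in {+1 (young), -1
(old)}^N, the selection problem is

    min ||w||_1   subject to   A w = y,

the linear-programming relaxation of the sparsest exact representation of
the labels by voxel columns. With the split w = u - v, u, v >= 0, this is a
standard non-negative LP solved with HiGHS. Columns are standardized to
zero mean and unit variance using training-subject statistics (the 1-norm is
scale-sensitive; unstandardized densities bias selection toward
high-variance voxels). Because zero-mean columns span only the subspace
orthogonal to the all-ones vector, y is centred by its training mean before
each solve; for balanced training sets this is a no-op.

### Why one LP is not a ranking

A basic solution of the LP supports at most N columns, and when informative
voxels are mutually redundant — whole clusters carrying the same signal —
the optimum keeps only a few interchangeable representatives per cluster
("over-pruning"). A single solve therefore cannot score every voxel.
We use the LP's dual certificate instead: at optimality every support
column j satisfies |a_j' lambda| = 1, and any column nearly interchangeable
with the support scores close to 1, while columns useless for representing
y score well below. The mean of |a_j' lambda| over `n_solves` LPs fitted on
balanced subject resamples (fraction `subsample_fraction` per class) is a
dense, stable importance score.

### The recursion and the weight ladder

Selection is recursive: each round scores the remaining voxels as above,
appends the `round_size` (default 200) highest-scoring voxels to the global
order, removes them, and re-solves. When the equality system becomes
infeasible, the remaining column count drops below the subsample size, or
`max_rounds` is hit, the remaining voxels are appended in decreasing |t|
order. The final order receives batch weights: with B batches of
`batch_size` consecutive voxels, batch b gets weight (B - b + 1)/B — at the
conventional scale (20,000 filtered voxels, batches of 200) the ladder is
1.00, 0.99, ..., 0.01.

### The full pipeline

1. **t filter.** Rank voxels by the pooled-variance two-sample t statistic
   (young minus old) and keep the `filter_k` largest by |t| (default
   20,000; ties broken by ascending flat index; zero-variance voxels score
   0). The statistic is a ranking filter only — no multiple-testing
   correction is involved.
2. **Recursive sparse selection** on the filtered columns, as above.
3. **Cross-validated consensus.** Steps 1-2 and classifier training run
   inside each of M stratified folds (default M = 10) on training subjects
   only; held-out subjects are transformed with training statistics. The
   consensus pattern is the intersection of the M filtered voxel sets
   ranked by the mean of the M batch weights, truncated to `pattern_size`
   (default 1,000). The intersection-of-folds construction is what repairs
   over-pruning: voxels that a single sparse solve would drop still earn
   high mean weight if every fold ranks their batch early.
4. **Classification.** Soft-margin linear SVM (C = 1 default) on
   standardized selected voxels; young is the positive class and the
   decision threshold is fixed at 0. Accuracy is reported as GR (overall),
   SS (sensitivity: correct young) and SC (specificity: correct old), as
   fractions and as one-decimal round-half-even percentages.
5. **Pattern application.** A fixed consensus pattern is validated on a
   second cohort on the same grid by leave-one-out CV restricted to the
   pattern voxels.
6. **Cluster reporting.** Connected components of the pattern (26-neighbour
   connectivity by default), per-cluster OLS of mean density on age with a
   two-sided slope t-test (alpha 0.05 default), the fraction of pattern
   voxels whose old-group mean lies below the young-group mean, and
   single-voxel versus voxel-pair CV accuracies with their decision
   boundaries.

## Synthetic cohorts

The generator emulates the *output* of a VBM preprocessing chain, not the
chain itself: per subject i and mask voxel j,

    x_ij = baseline + slope_j * age_i + loading_j * z_i + eps_ij,

with ages uniform in the group ranges (defaults 18-30 and 50-91 years),
`z` a per-pair latent factor shared between a direct cluster and its
covarying partner (sd `latent_sd`), and `eps` white noise (sd `noise_sd`)
smoothed with a Gaussian of `smooth_fwhm_voxels` FWHM. Smoothing is applied
to the noise only, so planted slopes and loadings stay exactly
interpretable. Clusters are spheres, optionally trimmed to an exact voxel
count nearest the centre; distinct clusters must be disjoint. Output is
bit-reproducible for a fixed spec.

Two benchmark cohorts ship with the package (200 subjects, 20 x 20 x 10
grid, 4,000 mask voxels, noise sd 0.05, FWHM 2):

- `recovery_demo_spec`: three direct clusters of 40 voxels at
  -0.01 density/yr plus a zero-slope control cluster.
- `default_demo_spec`: the same plus one covarying cluster (loading 0.1,
  slope -0.001/yr) sharing a latent factor (sd 2.0) with its direct partner
  (loading 0.25). These values put the covarying cluster in its defining
  regime: marginal effect size ~0.23 (undetectable univariately at this n),
  joint effect with the partner ~3.9 once the shared factor is cancelled.

What the generator does *not* emulate: cortical anatomy and folding,
registration and partial-volume artifacts, spatially varying noise, global
covariance beyond the planted factors, and the intensity distribution of
real GM maps. Passing recovery tests therefore shows the pipeline's
statistical machinery is correct under its own assumptions, not that real
cohorts would yield the same accuracy.

## Numerical choices

- LP feasibility tolerance 1e-7 on ||Aw - y||_inf; support tolerance 1e-8
  on |w_j|; infeasibility is an explicit status, not an exception.
- Ranking ties always break by ascending flat voxel index; voxel indices
  are 0-based, row-major over the grid.
- Subsamples draw max(2, round(fraction * class size)) subjects per class,
  seeded; every random element (folds, subsamples) derives from explicit
  seeds, and per-fold selection seeds are derived deterministically from
  the pipeline seed.
- SVC tolerance 1e-8 so label-flip antisymmetry holds to ~1e-6.
- Zero pooled-variance voxels get t = 0 with a warning (a constant voxel
  carries no discriminative signal); empty fold intersections yield an
  explicit empty pattern with a warning.
- NIfTI affines are carried through to written score maps but never
  interpreted; no atlas or anatomical labeling is in scope.

## Design decisions that were genuinely open

- **Dual-certificate scoring.** The round-wise importance could be read as
  "the LP support, ordered by |w|". That reading over-prunes redundant
  clusters (a handful of representatives per round) and cannot reproduce
  cluster-level recovery; the dual certificate is the same LP's own measure
  of how close each column is to the support and behaves like a dense
  version of the support indicator. Resampling subjects between solves
  de-biases the certificate from any single basic solution.
- **|t| versus signed t** for the filter: |t| (symmetric; configurable).
- **Pooled-variance t** rather than Welch: the classical two-sample filter.
- **Stratified folds** to preserve class balance in small cohorts; the CV
  seed is part of the configuration because the consensus depends on it.
- **Round size versus batch size.** Rounds select 200 voxels (the
  conventional per-round count); the weight ladder steps every
  `batch_size` voxels. At the conventional scale the two coincide.
- **Demo filter size.** The synthetic benchmarks run with `filter_k` equal
  to the full 4,000-voxel mask; sub-mask filters (500-2,000) were evaluated
  and do not change the benchmark outcomes.

## Known limitations

- The covarying-cluster *ranking* advantage of sparse selection over the
  univariate filter is fragile on this phantom: the t statistic already
  captures the covarying block's small marginal effect, while exact-fit
  L1 minimisation can satisfy its equality constraint cheaply with the
  abundant smoothed-noise columns instead of with factor-cancelling pairs.
  The pair-level synergy (pair accuracy far above either single voxel) is
  robust; the rank comparison holds at the canonical demo seed but not for
  every draw of the cohort.
- Runtime is dominated by the LP solves; the benchmark scale (200 x 4,000,
  ten folds) fits in a few minutes on one core, and the problem sizes used
  throughout the tests and the acceptance script were chosen at that scale.
- Labels are binary group codes; continuous-age sparse regression is out of
  scope, as is any preprocessing of real images (segmentation,
  normalisation, smoothing) and anatomical labeling.
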