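# sparsevbm

Sparse-representation multivariate pattern analysis (MVPA) of brain aging
from voxel-based morphometry (VBM) data.

Structural MRI cohorts show two kinds of age effects in gray-matter (GM)
density maps: regions whose volume declines directly with age — easy to
find with a voxelwise two-sample t-test — and regions whose change is
subtle but *covaries* with the directly affected regions, which univariate
tests miss. `sparsevbm` implements a two-step voxel-selection pipeline for
researchers analysing smoothed, normalised GM density maps of young and old
cohorts:

1. **t filter** — rank all mask voxels by the pooled-variance two-sample
   t statistic between young and old and keep the top *K*;
2. **recursive sparse selection** — treat the label vector
   y ∈ {+1 (young), −1 (old)}ᴺ as a sparse linear combination of voxel
   columns and solve

       min ‖w‖₁  subject to  A w = y

   as a non-negative linear program (w = u − v, u,v ≥ 0). Because a single
   sparse solution keeps only a few representatives of redundant clusters,
   voxels are scored by the LP's dual certificate |aⱼᵀλ| averaged over a
   few subject-resampled solves, and the selection proceeds in rounds of
   200 voxels that are removed before the next solve. The resulting order
   receives descending batch weights (1.00, 0.99, …, 0.01 at the
   conventional 20,000-voxel/batch-200 scale).

Selection and classifier training run inside every cross-validation fold;
the **consensus pattern** is the intersection of the per-fold voxel sets
ranked by mean fold weight. A linear soft-margin SVM (young = positive
class) scores held-out subjects, and accuracy is reported as the
generalization rate GR = (TP+TN)/N, sensitivity SS = TP/(TP+FN) (correct
young) and specificity SC = TN/(TN+FP) (correct old). Post-hoc reports
cover connected clusters of the pattern, per-cluster mean-volume-vs-age
regressions, decline fractions, and single-voxel versus voxel-pair
discrimination.

A seeded synthetic-cohort generator produces GM-density phantoms with
planted direct and covarying clusters (plus ground truth) so that every
stage is testable without any imaging data.

## Worked example

```python
import numpy as np
from sparsevbm import SparseAgingPattern, SyntheticSpec, ClusterSpec, generate_cohort

spec = SyntheticSpec(
    grid_shape=(16, 16, 8), n_young=40, n_old=40,
    noise_sd=0.05, smooth_fwhm_voxels=2.0, seed=0,
    clusters=[
        ClusterSpec("motor", center=(4, 4, 3), radius=2, age_slope=-0.01),
        ClusterSpec("caudate", center=(11, 11, 4), radius=2, age_slope=-0.01),
    ],
)
cohort, truth = generate_cohort(spec)
results = SparseAgingPattern(cohort, filter_k=2048, batch_size=50,
                             pattern_size=300, n_classify=100,
                             folds=5, seed=0).fit()
print(results.summary())
```

prints

```
Sparse Aging Pattern Results
============================================================
Subjects:            80 (40 young, 40 old)
Mask voxels:         2048
t-filter size:       2048
Batch size:          50
CV folds:            5 (seed 0)
SVM C:               1.0
------------------------------------------------------------
Consensus pattern:   300 voxels (requested 300)
Pooled CV metrics:   GR 100.0%  SS 100.0%  SC 100.0%
  confusion counts:  TP=40 FN=0 TN=40 FP=0
Score-age Pearson r: -0.9946
============================================================
```

Every held-out subject is classified correctly (GR/SS/SC 100%) using the
300-voxel consensus pattern, and the SVM decision score tracks
chronological age almost perfectly (r = −0.99; scores fall with age because
young is the positive class). The two largest connected clusters of the
pattern sit on the planted spheres and recover their decline:

```python
report = results.cluster_report()
print(report[report["size"] >= 10].round(5).to_string(index=False))
```

```
 cluster_id  size  centroid_x  centroid_y  centroid_z  slope_b  slope_se  p_value  declines  representative_voxel
          0   157     5.22293     4.79618     3.54140 -0.00210   0.00001      0.0      True                   410
          1    85    11.69412    10.14118     3.62353 -0.00389   0.00001      0.0      True                  1365
```

`slope_b` is the OLS coefficient of mean cluster density on age in density
units per year; both clusters decline significantly (the cluster means mix
planted voxels with adjacent selected voxels, so the slopes lie between the
planted −0.01 and 0).

A second cohort on the same grid can be scored with the fixed pattern via
`results.apply(cohort2)` (leave-one-out CV), and
`results.accuracy_curve([100, 200, 500])` traces GR against the number of
top-ranked voxels.

## Command line

```sh
sparsevbm simulate spec.yaml --out data/        # NIfTI volumes + subjects.tsv + ground truth
sparsevbm select data/ --config cfg.yaml --out run/   # consensus pattern TSV/NIfTI + JSON report
sparsevbm classify data2/ --pattern run/consensus_pattern.tsv
```

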