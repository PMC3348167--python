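"""Fold construction, leakage safety, consensus pattern, LOOCV transfer."""

import warnings

import numpy as np
import pytest

from sparsevbm.crossval import (
    PipelineParams,
    accuracy_vs_nvoxels,
    apply_pattern,
    consensus_pattern,
    loocv_metrics,
    make_folds,
    run_cv,
    run_fold,
)
from sparsevbm.sparse import BatchWeighting, assign_batch_weights


def small_params(**over):
    base = dict(filter_k=50, batch_size=5, pattern_size=20, n_classify=10,
                folds=4, seed=0)
    base.update(over)
    return PipelineParams(**base)


class TestMakeFolds:
    def test_balanced_stratified_folds(self):
        labels = np.array([1] * 10 + [-1] * 10)
        plan = make_folds(labels, 10, seed=0)
        for m in range(10):
            test = plan.test_indices(m)
            assert len(test) == 2
            assert labels[test].sum() == 0  # one young + one old

    def test_loocv_singletons(self):
        labels = np.array([1] * 4 + [-1] * 4)
        plan = make_folds(labels, 8, seed=1)
        sizes = [len(plan.test_indices(m)) for m in range(8)]
        assert sizes == [1] * 8

    def test_seed_determinism_and_variation(self):
        labels = np.array([1] * 12 + [-1] * 12)
        a = make_folds(labels, 4, seed=5).assignments
        b = make_folds(labels, 4, seed=5).assignments
        c = make_folds(labels, 4, seed=6).assignments
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_partition_property(self):
        labels = np.array([1] * 9 + [-1] * 7)
        plan = make_folds(labels, 3, seed=2)
        all_test = np.concatenate([plan.test_indices(m) for m in range(3)])
        assert sorted(all_test.tolist()) == list(range(16))
        # within-class sizes differ by at most one
        for cls in (1, -1):
            counts = [np.sum(labels[plan.test_indices(m)] == cls) for m in range(3)]
            assert max(counts) - min(counts) <= 1

    def test_class_smaller_than_m_rejected(self):
        labels = np.array([1] * 2 + [-1] * 10)
        with pytest.raises(ValueError, match="fewer than"):
            make_folds(labels, 5, seed=0)
        make_folds(labels, 5, seed=0, allow_small_classes=True)


class TestRunFold:
    def test_noiseless_separable_cohort_perfect_heldout(self, separable_cohort):
        params = small_params()
        plan = make_folds(separable_cohort.labels, 4, seed=0)
        for m in range(4):
            fr = run_fold(separable_cohort, plan, m, params)
            assert fr.metrics.GR == 1.0

    def test_heldout_subjects_never_in_training(self, separable_cohort):
        plan = make_folds(separable_cohort.labels, 4, seed=1)
        for m in range(4):
            assert not set(plan.test_indices(m)) & set(plan.train_indices(m))

    def test_selection_blind_to_heldout_subjects(self, separable_cohort):
        """Poisoning held-out rows must not change selection or weights."""
        params = small_params()
        plan = make_folds(separable_cohort.labels, 4, seed=2)
        fr_clean = run_fold(separable_cohort, plan, 0, params)
        poisoned = separable_cohort.subset(np.arange(separable_cohort.n_subjects))
        poisoned.X = poisoned.X.copy()
        poisoned.X[plan.test_indices(0)] = 1e6
        fr_poisoned = run_fold(poisoned, plan, 0, params)
        assert np.array_equal(fr_clean.weighting.order, fr_poisoned.weighting.order)
        assert np.array_equal(fr_clean.filtered.order, fr_poisoned.filtered.order)

    def test_fold_confusions_pool_to_whole_cohort(self, separable_cohort):
        params = small_params()
        cv = run_cv(separable_cohort, params)
        pooled = cv.pooled_metrics
        assert pooled.n == separable_cohort.n_subjects
        idx, scores = cv.pooled_scores
        assert np.array_equal(idx, np.arange(separable_cohort.n_subjects))


class TestConsensusPattern:
    def test_identical_weightings_reproduce_ordering(self):
        bw = assign_batch_weights(np.array([4, 2, 7, 1, 9]), 2)
        pattern = consensus_pattern([bw, bw, bw], top_n=3)
        assert pattern.voxels.tolist() == [2, 4, 1]  # weight ties break by index
        assert np.all(pattern.fold_presence == 3)

    def test_disjoint_folds_give_empty_pattern_with_warning(self):
        bw1 = assign_batch_weights(np.array([0, 1]), 1)
        bw2 = assign_batch_weights(np.array([2, 3]), 1)
        with pytest.warns(UserWarning, match="empty"):
            pattern = consensus_pattern([bw1, bw2], top_n=2)
        assert len(pattern) == 0

    def test_hand_worked_mean_weight_ordering(self):
        # three folds over 5 voxels with hand-set batch weights
        w1 = BatchWeighting(order=np.array([0, 1, 2, 3, 4]),
                            weights=np.array([1.0, 1.0, 0.5, 0.5, 0.25]),
                            batch_size=2)
        w2 = BatchWeighting(order=np.array([1, 0, 4, 2, 3]),
                            weights=np.array([1.0, 1.0, 0.5, 0.5, 0.25]),
                            batch_size=2)
        w3 = BatchWeighting(order=np.array([1, 4, 0, 3, 2]),
                            weights=np.array([1.0, 1.0, 0.5, 0.5, 0.25]),
                            batch_size=2)
        pattern = consensus_pattern([w1, w2, w3], top_n=5)
        # hand means: v0 (1+1+.5)/3=.8333, v1 1.0, v2 (.5+.5+.25)/3=.4167,
        #             v3 (.5+.25+.5)/3=.4167, v4 (.25+.5+1)/3=.5833
        assert pattern.voxels.tolist() == [1, 0, 4, 2, 3]
        assert pattern.mean_weight[0] == pytest.approx(1.0)
        assert pattern.mean_weight[1] == pytest.approx(2.5 / 3)

    def test_short_intersection_warns_and_returns_all(self):
        bw1 = assign_batch_weights(np.array([0, 1, 2]), 1)
        bw2 = assign_batch_weights(np.array([1, 2, 3]), 1)
        with pytest.warns(UserWarning, match="survive"):
            pattern = consensus_pattern([bw1, bw2], top_n=10)
        assert set(pattern.voxels.tolist()) == {1, 2}


class TestApplyPattern:
    def test_self_application_of_separable_pattern(self, separable_cohort):
        cv = run_cv(separable_cohort, small_params())
        metrics, scores = apply_pattern(cv.pattern, separable_cohort)
        assert metrics.GR == 1.0
        assert len(scores) == separable_cohort.n_subjects

    def test_pattern_voxel_outside_mask_rejected(self, separable_cohort):
        cv = run_cv(separable_cohort, small_params())
        small = separable_cohort.subset(np.arange(separable_cohort.n_subjects))
        small.X = small.X[:, :3]
        from sparsevbm.io import BrainMask, Cohort
        cohort2 = Cohort(
            X=small.X,
            ages=small.ages,
            labels=small.labels,
            mask=BrainMask(in_mask=np.ones((3, 1, 1), dtype=bool)),
        )
        with pytest.raises(ValueError, match="resolvable"):
            apply_pattern(cv.pattern, cohort2)

    def test_loocv_on_fixed_voxels(self, separable_cohort):
        metrics, scores = loocv_metrics(separable_cohort, np.array([3, 17, 30]))
        assert metrics.GR == 1.0


class TestAccuracyVsNvoxels:
    def test_reaches_one_on_separable_cohort(self, separable_cohort):
        params = small_params()
        curve = accuracy_vs_nvoxels(separable_cohort, [5, 20], params,
                                    method="sparse")
        assert curve[0][1] == 1.0
        assert curve[1][1] == 1.0

    def test_deterministic_and_bounded(self, separable_cohort):
        params = small_params()
        c1 = accuracy_vs_nvoxels(separable_cohort, [10], params, method="ttest")
        c2 = accuracy_vs_nvoxels(separable_cohort, [10], params, method="ttest")
        assert c1 == c2
        with pytest.raises(ValueError, match="exceeds"):
            accuracy_vs_nvoxels(separable_cohort, [1000], params)
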