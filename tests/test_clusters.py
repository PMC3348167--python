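"""Connected components, cluster age regression, decline fraction, pair
discrimination."""

import numpy as np
import pytest
from scipy import stats

from sparsevbm.clusters import (
    ClusterSummary,
    cluster_age_regression,
    connected_clusters,
    pairwise_voxel_discrimination,
    volume_change_fraction,
)
from sparsevbm.crossval import make_folds
from sparsevbm.io import BrainMask, Cohort


@pytest.fixture()
def full_mask():
    return BrainMask(in_mask=np.ones((8, 8, 8), dtype=bool))


def flood_fill_components(coords, connectivity):
    """Brute-force oracle: connected components by BFS over a coordinate set."""
    coords = {tuple(c) for c in coords}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    if connectivity == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    elif connectivity == 18:
        offsets = [o for o in offsets if sum(map(abs, o)) <= 2]
    comps, seen = [], set()
    for start in coords:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            c = queue.pop()
            if c in comp:
                continue
            comp.add(c)
            for o in offsets:
                nb = tuple(np.add(c, o))
                if nb in coords and nb not in comp:
                    queue.append(nb)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestConnectedClusters:
    def test_isolated_voxel_single_cluster(self, full_mask):
        voxels = full_mask.flatten(np.array([[4, 4, 4]]))
        out = connected_clusters(voxels, full_mask)
        assert len(out) == 1 and out[0].size == 1

    def test_connectivity_semantics(self, full_mask):
        face = full_mask.flatten(np.array([[2, 2, 2], [2, 2, 3]]))
        diag = full_mask.flatten(np.array([[2, 2, 2], [3, 3, 3]]))
        assert len(connected_clusters(face, full_mask, connectivity=6)) == 1
        assert len(connected_clusters(diag, full_mask, connectivity=6)) == 2
        assert len(connected_clusters(diag, full_mask, connectivity=26)) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, full_mask, connectivity):
        rng = np.random.default_rng(9)
        voxels = rng.choice(full_mask.n_voxels, size=20, replace=False)
        out = connected_clusters(np.sort(voxels), full_mask, connectivity)
        got = {
            frozenset(map(tuple, full_mask.unflatten(c.voxels))) for c in out
        }
        expected = flood_fill_components(full_mask.unflatten(voxels), connectivity)
        assert got == expected

    def test_partition_and_size_ordering(self, full_mask):
        rng = np.random.default_rng(4)
        voxels = np.sort(rng.choice(full_mask.n_voxels, size=40, replace=False))
        out = connected_clusters(voxels, full_mask)
        combined = np.sort(np.concatenate([c.voxels for c in out]))
        assert np.array_equal(combined, voxels)
        sizes = [c.size for c in out]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_pattern_warns(self, full_mask):
        with pytest.warns(UserWarning, match="empty"):
            assert connected_clusters(np.array([], dtype=int), full_mask) == []


def _cohort(X, ages, labels):
    mask = BrainMask(in_mask=np.ones((X.shape[1], 1, 1), dtype=bool))
    return Cohort(X=X, ages=ages, labels=labels, mask=mask)


class TestClusterAgeRegression:
    def _cluster(self, voxels):
        return ClusterSummary(cluster_id=0, voxels=np.asarray(voxels),
                              centroid=(0, 0, 0))

    def test_noiseless_line_recovered(self):
        ages = np.linspace(20, 80, 30)
        X = (2.0 - 0.01 * ages)[:, None] * np.ones((1, 4))
        labels = np.where(ages < 40, 1, -1)
        c = cluster_age_regression(_cohort(X, ages, labels), self._cluster([0, 1]))
        assert c.slope == pytest.approx(-0.01, abs=1e-12)
        assert c.slope_p < 1e-20
        assert c.declines

    def test_constant_volume_null(self):
        ages = np.linspace(20, 80, 30)
        X = np.full((30, 3), 0.7)
        labels = np.where(ages < 40, 1, -1)
        c = cluster_age_regression(_cohort(X, ages, labels), self._cluster([1]))
        assert c.slope == pytest.approx(0.0, abs=1e-12)
        assert not c.declines

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(20, 90, 40)
        X = rng.normal(size=(40, 5))
        labels = np.where(ages < 50, 1, -1)
        c = cluster_age_regression(_cohort(X, ages, labels),
                                   self._cluster([0, 2, 4]))
        yv = X[:, [0, 2, 4]].mean(axis=1)
        A = np.column_stack([np.ones_like(ages), ages])
        beta = np.linalg.solve(A.T @ A, A.T @ yv)
        resid = yv - A @ beta
        s2 = resid @ resid / (len(ages) - 2)
        se = np.sqrt(s2 * np.linalg.inv(A.T @ A)[1, 1])
        tstat = beta[1] / se
        p = 2 * stats.t.sf(abs(tstat), len(ages) - 2)
        assert c.slope == pytest.approx(beta[1], abs=1e-10)
        assert c.slope_se == pytest.approx(se, abs=1e-10)
        assert c.slope_p == pytest.approx(p, abs=1e-10)

    def test_zero_age_variance_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        labels = np.array([1, 1, 1, -1, -1, -1])
        with pytest.raises(ValueError, match="age variance"):
            cluster_age_regression(_cohort(X, np.full(6, 50.0), labels),
                                   self._cluster([0]))


class TestVolumeChangeFraction:
    def test_planted_decline_fraction_one(self):
        ages = np.concatenate([np.full(10, 25.0), np.full(10, 70.0)])
        labels = np.array([1] * 10 + [-1] * 10)
        X = (2.0 - 0.01 * ages)[:, None] * np.ones((1, 6))
        assert volume_change_fraction(np.arange(6), _cohort(X, ages, labels)) == 1.0

    def test_label_permutation_near_half(self):
        rng = np.random.default_rng(0)
        n, v = 100, 400
        X = rng.normal(size=(n, v))
        ages = np.concatenate([rng.uniform(18, 30, 50), rng.uniform(50, 91, 50)])
        labels = np.array([1] * 50 + [-1] * 50)
        frac = volume_change_fraction(np.arange(v), _cohort(X, ages, labels))
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(v)

    def test_empty_pattern_warns_and_returns_zero(self, full_mask):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, full_mask.n_voxels))
        ages = np.array([20, 25, 22, 70, 75, 80.0])
        labels = np.array([1, 1, 1, -1, -1, -1])
        cohort = Cohort(X=X, ages=ages, labels=labels, mask=full_mask)
        with pytest.warns(UserWarning, match="empty"):
            assert volume_change_fraction(np.array([], dtype=int), cohort) == 0.0


class TestPairwiseVoxelDiscrimination:
    def test_identical_voxels_rejected(self, small_cohort):
        cohort, _ = small_cohort
        plan = make_folds(cohort.labels, 4, seed=0)
        with pytest.raises(ValueError, match="distinct"):
            pairwise_voxel_discrimination(cohort, 5, 5, plan)

    def test_noise_voxels_near_chance(self, small_cohort):
        cohort, truth = small_cohort
        planted = np.concatenate(list(truth.cluster_voxels.values()))
        noise = np.setdiff1d(np.arange(cohort.n_voxels), planted)
        plan = make_folds(cohort.labels, 4, seed=1)
        out = pairwise_voxel_discrimination(
            cohort, int(noise[10]), int(noise[500]), plan
        )
        for acc in (out.accuracy_a, out.accuracy_b, out.accuracy_pair):
            assert 0.2 <= acc <= 0.8

    def test_partnered_pair_shows_synergy(self, small_cohort):
        cohort, truth = small_cohort
        plan = make_folds(cohort.labels, 4, seed=2)
        out = pairwise_voxel_discrimination(
            cohort,
            int(truth.cluster_voxels["direct"][0]),
            int(truth.cluster_voxels["covary"][0]),
            plan,
        )
        assert out.accuracy_pair > max(out.accuracy_a, out.accuracy_b)
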