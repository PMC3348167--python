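"""Post-hoc characterisation of the selected aging pattern.

Connected clusters of pattern voxels, per-cluster mean-volume-versus-age
regression with a slope hypothesis test, the fraction of pattern voxels
whose volume is lower in the old group, and the single-voxel versus
voxel-pair discrimination comparison that exposes covarying structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .classify import confusion_and_metrics, train_margin_classifier
from .crossval import ConsensusPattern, FoldPlan
from .io import BrainMask, Cohort

__all__ = [
    "ClusterSummary",
    "connected_clusters",
    "cluster_age_regression",
    "volume_change_fraction",
    "pairwise_voxel_discrimination",
    "PairDiscrimination",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterSummary:
    """One connected cluster of pattern voxels, with its age regression."""

    cluster_id: int
    voxels: np.ndarray  # flat voxel indices
    centroid: tuple[float, float, float]
    slope: float | None = None  # density units per year
    slope_se: float | None = None
    slope_p: float | None = None
    declines: bool | None = None
    representative: int | None = None  # voxel with peak consensus weight

    @property
    def size(self) -> int:
        return len(self.voxels)


def connected_clusters(
    pattern: ConsensusPattern | np.ndarray,
    mask: BrainMask,
    connectivity: int = 26,
) -> list[ClusterSummary]:
    """Connected components of the pattern's voxel set, largest first.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (all neighbours);
    ties in size are broken by the smallest flat voxel index.  When given a
    :class:`ConsensusPattern`, each cluster's representative voxel is the
    one with the highest consensus weight.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    if isinstance(pattern, ConsensusPattern):
        voxels = pattern.voxels
        weight = dict(zip(pattern.voxels.tolist(), pattern.mean_weight.tolist()))
    else:
        voxels = np.asarray(pattern, dtype=int)
        weight = None
    if voxels.size == 0:
        warnings.warn("empty pattern: no clusters", stacklevel=2)
        return []

    binary = mask.insert(np.isin(np.arange(mask.n_voxels), voxels).astype(float)) > 0
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_comp = ndimage.label(binary, structure=structure)

    summaries = []
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labels == comp)
        flat = np.sort(mask.flatten(coords))
        rep = None
        if weight is not None:
            # deterministic: peak weight, ties by ascending flat index
            rep = int(min(flat, key=lambda v: (-weight[v], v)))
        summaries.append(
            ClusterSummary(
                cluster_id=-1,
                voxels=flat,
                centroid=tuple(coords.mean(axis=0)),
                representative=rep,
            )
        )
    summaries.sort(key=lambda c: (-c.size, int(c.voxels[0])))
    for i, c in enumerate(summaries):
        c.cluster_id = i
    return summaries


def cluster_age_regression(
    cohort: Cohort, cluster: ClusterSummary, alpha: float = 0.05
) -> ClusterSummary:
    """OLS of per-subject mean cluster density on age, with a slope t-test.

    Fills the cluster's ``slope`` (density units/yr), its standard error,
    the two-sided p-value of the slope, and ``declines`` (negative slope
    significant at ``alpha``).
    """
    if cohort.n_subjects < 3:
        raise ValueError("need at least 3 subjects for the regression")
    if np.std(cohort.ages) == 0:
        raise ValueError("zero age variance")
    mean_volume = cohort.X[:, cluster.voxels].mean(axis=1)
    fit = stats.linregress(cohort.ages, mean_volume)
    cluster.slope = float(fit.slope)
    cluster.slope_se = float(fit.stderr)
    cluster.slope_p = float(fit.pvalue)
    cluster.declines = bool(fit.slope < 0 and fit.pvalue < alpha)
    return cluster


def volume_change_fraction(
    pattern: ConsensusPattern | np.ndarray, cohort: Cohort
) -> float:
    """Fraction of pattern voxels whose old-group mean density is below the
    young-group mean (ties count as non-decreasing)."""
    voxels = pattern.voxels if isinstance(pattern, ConsensusPattern) else np.asarray(pattern)
    if voxels.size == 0:
        warnings.warn("empty pattern: decline fraction over 0 voxels", stacklevel=2)
        return 0.0
    young = cohort.X[cohort.labels == 1][:, voxels].mean(axis=0)
    old = cohort.X[cohort.labels == -1][:, voxels].mean(axis=0)
    if not (len(young) and len(old)):
        raise ValueError("both groups must be present")
    return float(np.mean(old < young))


@dataclass
class PairDiscrimination:
    """CV accuracies of two single voxels and their pair, with the three
    decision boundaries (weights, bias) for plotting."""

    accuracy_a: float
    accuracy_b: float
    accuracy_pair: float
    boundary_a: tuple[np.ndarray, float]
    boundary_b: tuple[np.ndarray, float]
    boundary_pair: tuple[np.ndarray, float]

    @property
    def synergy(self) -> float:
        """Pair accuracy minus the best single-voxel accuracy."""
        return self.accuracy_pair - max(self.accuracy_a, self.accuracy_b)


def pairwise_voxel_discrimination(
    cohort: Cohort,
    voxel_a: int,
    voxel_b: int,
    plan: FoldPlan,
    C: float = 1.0,
) -> PairDiscrimination:
    """Compare the discrimination of two single voxels with their pair.

    Cross-validated GR of the margin classifier on the feature sets {a},
    {b} and {a, b}; a pair accuracy exceeding both singles indicates that
    the two voxels carry covarying (jointly discriminative) information.
    """
    if voxel_a == voxel_b:
        raise ValueError("voxel_a and voxel_b must be distinct")
    for v in (voxel_a, voxel_b):
        if not 0 <= v < cohort.n_voxels:
            raise IndexError(f"voxel {v} outside the mask")

    def cv_gr(cols: list[int]) -> float:
        total = None
        for m in range(plan.M):
            tr, te = plan.train_indices(m), plan.test_indices(m)
            model = train_margin_classifier(
                cohort.X[np.ix_(tr, cols)], cohort.labels[tr], C=C
            )
            cm = confusion_and_metrics(
                cohort.labels[te], model.predict(cohort.X[np.ix_(te, cols)])
            )
            total = cm if total is None else total + cm
        return total.GR

    def boundary(cols: list[int]) -> tuple[np.ndarray, float]:
        model = train_margin_classifier(cohort.X[:, cols], cohort.labels, C=C)
        return model.weights, model.bias

    return PairDiscrimination(
        accuracy_a=cv_gr([voxel_a]),
        accuracy_b=cv_gr([voxel_b]),
        accuracy_pair=cv_gr([voxel_a, voxel_b]),
        boundary_a=boundary([voxel_a]),
        boundary_b=boundary([voxel_b]),
        boundary_pair=boundary([voxel_a, voxel_b]),
    )
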