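"""Univariate voxel ranking: two-sample t filter.

The first selection step ranks every mask voxel by a classical
pooled-variance two-sample t statistic between the young and old groups and
retains the top K by absolute value.  No multiple-testing correction is
applied — the statistic is used purely as a ranking filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Cohort

__all__ = ["RankedVoxels", "voxelwise_tscore", "filter_top_k", "DEFAULT_FILTER_K"]

#: conventional size of the first-step filter on real whole-brain data
DEFAULT_FILTER_K = 20_000


@dataclass
class RankedVoxels:
    """Ordered voxel indices, most informative first, with aligned scores."""

    order: np.ndarray
    scores: np.ndarray
    score_kind: str  # "tscore" | "sparse_weight"

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.order.shape != self.scores.shape:
            raise ValueError("order and scores must be aligned")
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("duplicate voxel indices in ranking")

    def __len__(self) -> int:
        return len(self.order)

    def top(self, n: int) -> np.ndarray:
        if n > len(self):
            raise ValueError(f"requested {n} voxels from a ranking of {len(self)}")
        return self.order[:n]


def voxelwise_tscore(cohort: Cohort) -> np.ndarray:
    """Pooled-variance two-sample t per voxel, young minus old.

    Voxels with zero pooled variance are scored 0 (a constant voxel carries
    no discriminative signal) with a warning.
    """
    young = cohort.X[cohort.labels == 1]
    old = cohort.X[cohort.labels == -1]
    n1, n2 = len(young), len(old)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 subjects (got young={n1}, old={n2})")
    diff = young.mean(axis=0) - old.mean(axis=0)
    ss1 = young.var(axis=0, ddof=1)
    ss2 = old.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * ss1 + (n2 - 1) * ss2) / (n1 + n2 - 2)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(diff)
    nonzero = denom > 0
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} voxels have zero pooled variance; t set to 0",
            stacklevel=2,
        )
    t[nonzero] = diff[nonzero] / denom[nonzero]
    return t


def filter_top_k(tscores: np.ndarray, k: int, by_abs: bool = True) -> RankedVoxels:
    """Retain the k voxels with the largest |t| (ties: ascending flat index)."""
    tscores = np.asarray(tscores, dtype=float)
    v = tscores.size
    if not 1 <= k <= v:
        raise ValueError(f"k must be in [1, {v}], got {k}")
    key = np.abs(tscores) if by_abs else tscores
    # stable sort on descending key keeps ascending-index tie-break
    order = np.argsort(-key, kind="stable")[:k]
    return RankedVoxels(order=order, scores=tscores[order], score_kind="tscore")
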