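"""Model/Results interface over the sparse aging-pattern pipeline.

`SparseAgingPattern` is constructed from a :class:`~sparsevbm.io.Cohort`
(or raw arrays) plus pipeline parameters; :meth:`fit` runs the full
cross-validated selection and returns a results object carrying the
consensus pattern, per-fold and pooled confusion metrics, and post-hoc
summaries (cluster report, accuracy curves, score-age correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import score_age_correlation
from .clusters import (
    ClusterSummary,
    cluster_age_regression,
    connected_clusters,
    volume_change_fraction,
)
from .crossval import (
    CVResult,
    PipelineParams,
    accuracy_vs_nvoxels,
    apply_pattern,
    run_cv,
)
from .io import BrainMask, Cohort

__all__ = ["SparseAgingPattern", "SparseAgingPatternResults"]


class SparseAgingPattern:
    """Sparse-representation MVPA model of brain aging.

    Parameters
    ----------
    cohort
        Subject-by-voxel GM density data with ages and young/old labels.
    filter_k
        Voxels retained by the first-step t filter (capped at the mask size).
    batch_size
        Voxels per weighting batch in the recursive sparse selection.
    pattern_size
        Size of the final consensus pattern.
    folds
        Number of cross-validation folds (M).
    C
        Soft-margin constant of the linear SVM.
    seed
        Seed of the fold assignment (the consensus pattern depends on it).
    """

    def __init__(
        self,
        cohort: Cohort,
        filter_k: int = 20_000,
        batch_size: int = 200,
        pattern_size: int = 1_000,
        n_classify: int | None = None,
        folds: int = 10,
        C: float = 1.0,
        seed: int = 0,
        round_size: int = 200,
        n_solves: int = 2,
        subsample_fraction: float = 0.45,
        max_rounds: int | None = None,
    ) -> None:
        self.cohort = cohort
        self.params = PipelineParams(
            filter_k=filter_k,
            batch_size=batch_size,
            pattern_size=pattern_size,
            n_classify=pattern_size if n_classify is None else n_classify,
            folds=folds,
            C=C,
            seed=seed,
            round_size=round_size,
            n_solves=n_solves,
            subsample_fraction=subsample_fraction,
            max_rounds=max_rounds,
        )

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        ages: np.ndarray,
        labels: np.ndarray,
        mask: BrainMask | None = None,
        **params,
    ) -> "SparseAgingPattern":
        """Build the model from a plain matrix; a full-grid mask of shape
        (V, 1, 1) is assumed when none is given."""
        X = np.asarray(X, dtype=float)
        if mask is None:
            mask = BrainMask(in_mask=np.ones((X.shape[1], 1, 1), dtype=bool))
        cohort = Cohort(X=X, ages=np.asarray(ages, float),
                        labels=np.asarray(labels, int), mask=mask)
        return cls(cohort, **params)

    def fit(self) -> "SparseAgingPatternResults":
        cv = run_cv(self.cohort, self.params)
        return SparseAgingPatternResults(model=self, cv=cv)


@dataclass
class SparseAgingPatternResults:
    """Fitted pipeline: consensus pattern, CV metrics, post-hoc reports."""

    model: SparseAgingPattern
    cv: CVResult
    _clusters: list[ClusterSummary] | None = field(default=None, repr=False)

    @property
    def pattern(self):
        return self.cv.pattern

    @property
    def pooled_metrics(self):
        return self.cv.pooled_metrics

    @property
    def fold_metrics(self):
        return [f.metrics for f in self.cv.folds]

    @property
    def cv_scores(self) -> np.ndarray:
        """Held-out decision scores in subject order."""
        _, scores = self.cv.pooled_scores
        return scores

    def score_age_correlation(self) -> float:
        """Pearson r between held-out SVM scores and chronological age."""
        return score_age_correlation(self.cv_scores, self.model.cohort.ages)

    def cluster_report(
        self, connectivity: int = 26, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Connected clusters of the pattern with their age regressions."""
        clusters = connected_clusters(
            self.pattern, self.model.cohort.mask, connectivity=connectivity
        )
        for c in clusters:
            cluster_age_regression(self.model.cohort, c, alpha=alpha)
        self._clusters = clusters
        rows = [
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "centroid_z": c.centroid[2],
                "slope_b": c.slope,
                "slope_se": c.slope_se,
                "p_value": c.slope_p,
                "declines": c.declines,
                "representative_voxel": c.representative,
            }
            for c in clusters
        ]
        return pd.DataFrame(rows)

    def clusters(self, connectivity: int = 26, alpha: float = 0.05) -> list[ClusterSummary]:
        if self._clusters is None:
            self.cluster_report(connectivity=connectivity, alpha=alpha)
        return self._clusters

    def decline_fraction(self) -> float:
        """Fraction of pattern voxels with lower mean volume in the old group."""
        return volume_change_fraction(self.pattern, self.model.cohort)

    def apply(self, cohort2: Cohort):
        """Validate the consensus pattern on a second cohort by LOOCV."""
        return apply_pattern(self.pattern, cohort2, C=self.model.params.C)

    def accuracy_curve(self, n_grid: list[int], method: str = "sparse"):
        """Cross-validated GR versus number of top-ranked voxels."""
        return accuracy_vs_nvoxels(
            self.model.cohort, n_grid, self.model.params, method=method
        )

    def pattern_frame(self) -> pd.DataFrame:
        """Consensus pattern as a table (flat index, grid coords, weight)."""
        coords = self.model.cohort.mask.unflatten(self.pattern.voxels)
        return pd.DataFrame(
            {
                "voxel_flat_index": self.pattern.voxels,
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
                "mean_weight": self.pattern.mean_weight,
                "fold_presence": self.pattern.fold_presence,
            }
        )

    def summary(self) -> str:
        p = self.model.params
        cm = self.pooled_metrics
        lines = [
            "Sparse Aging Pattern Results",
            "=" * 60,
            f"Subjects:            {self.model.cohort.n_subjects} "
            f"({int((self.model.cohort.labels == 1).sum())} young, "
            f"{int((self.model.cohort.labels == -1).sum())} old)",
            f"Mask voxels:         {self.model.cohort.n_voxels}",
            f"t-filter size:       {min(p.filter_k, self.model.cohort.n_voxels)}",
            f"Batch size:          {p.batch_size}",
            f"CV folds:            {p.folds} (seed {p.seed})",
            f"SVM C:               {p.C}",
            "-" * 60,
            f"Consensus pattern:   {len(self.pattern)} voxels "
            f"(requested {p.pattern_size})",
            f"Pooled CV metrics:   GR {cm.GR_percent}%  SS {cm.SS_percent}%  "
            f"SC {cm.SC_percent}%",
            f"  confusion counts:  TP={cm.TP} FN={cm.FN} TN={cm.TN} FP={cm.FP}",
            f"Score-age Pearson r: {self.score_age_correlation():.4f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_accuracy_curve(self, curves: dict[str, list[tuple[int, float]]], ax=None):
        """Plot GR-versus-voxel-count curves (one line per labelled method)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, curve in curves.items():
            ns, grs = zip(*curve)
            ax.plot(ns, grs, marker="o", label=label)
        ax.set_xlabel("number of voxels")
        ax.set_ylabel("classification accuracy (GR)")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax

    def plot_score_vs_age(self, ax=None):
        """Scatter of held-out decision scores against age."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ages = self.model.cohort.ages
        scores = self.cv_scores
        young = self.model.cohort.labels == 1
        ax.scatter(ages[young], scores[young], marker="*", label="young")
        ax.scatter(ages[~young], scores[~young], marker="x", label="old")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("SVM decision score")
        ax.legend()
        return ax
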