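"""Cross-validated voxel selection and the consensus aging pattern.

The pipeline runs M-fold cross-validation in which BOTH the voxel selection
(t filter then recursive sparse selection) and the classifier are fitted on
the training part of each fold only; held-out subjects are transformed with
training-fold statistics.  Each fold yields one batch weighting of its
filtered voxels.  The consensus pattern is the intersection of the M
filtered voxel sets, ranked by the mean of the M fold weights — the voxels
that survive selection in every fold, which corrects the over-pruning of any
single sparse solve.  The pattern can then be applied to an independent
second cohort, scored by leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import ConfusionMetrics, confusion_and_metrics, train_margin_classifier
from .io import Cohort
from .sparse import BatchWeighting, recursive_select, DEFAULT_BATCH_SIZE
from .tstats import RankedVoxels, filter_top_k, voxelwise_tscore, DEFAULT_FILTER_K

__all__ = [
    "FoldPlan",
    "PipelineParams",
    "FoldResult",
    "ConsensusPattern",
    "CVResult",
    "make_folds",
    "run_fold",
    "run_cv",
    "consensus_pattern",
    "apply_pattern",
    "accuracy_vs_nvoxels",
    "loocv_metrics",
]

DEFAULT_PATTERN_SIZE = 1_000


@dataclass(frozen=True)
class FoldPlan:
    """Stratified partition of subjects into M folds."""

    M: int
    assignments: np.ndarray  # fold id per subject, 0..M-1
    seed: int

    def train_indices(self, fold_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold_id)

    def test_indices(self, fold_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold_id)


def make_folds(
    labels: np.ndarray, M: int, seed: int, allow_small_classes: bool = False
) -> FoldPlan:
    """Seeded stratified M-fold partition; M = N gives leave-one-out.

    Within each class, fold sizes differ by at most one; classes are dealt
    onto a shuffled fold cycle with a running offset so total fold sizes are
    balanced too.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if not 2 <= M <= n:
        raise ValueError(f"M must be in [2, {n}], got {M}")
    rng = np.random.default_rng(seed)
    assignments = np.full(n, -1, dtype=int)
    fold_cycle = rng.permutation(M)
    offset = 0
    for cls in (1, -1):
        members = np.flatnonzero(labels == cls)
        if M < n and members.size < M and not allow_small_classes:
            raise ValueError(
                f"class {cls} has {members.size} subjects, fewer than M={M} folds "
                "(pass allow_small_classes=True to override)"
            )
        members = rng.permutation(members)
        for i, subject in enumerate(members):
            assignments[subject] = fold_cycle[(offset + i) % M]
        offset += members.size
    return FoldPlan(M=M, assignments=assignments, seed=seed)


@dataclass
class PipelineParams:
    """Tunable parameters of the selection/classification pipeline."""

    filter_k: int = DEFAULT_FILTER_K
    batch_size: int = DEFAULT_BATCH_SIZE
    pattern_size: int = DEFAULT_PATTERN_SIZE
    n_classify: int = DEFAULT_PATTERN_SIZE  # voxels used for per-fold metrics
    folds: int = 10
    C: float = 1.0
    seed: int = 0
    rank_by_abs_t: bool = True
    round_size: int = 200
    n_solves: int = 2
    subsample_fraction: float = 0.45
    max_rounds: int | None = None


@dataclass
class FoldResult:
    fold_id: int
    filtered: RankedVoxels  # in-fold t ranking (flat voxel indices)
    weighting: BatchWeighting  # order/weights over flat voxel indices
    metrics: ConfusionMetrics
    test_indices: np.ndarray
    test_scores: np.ndarray
    test_pred: np.ndarray


@dataclass
class ConsensusPattern:
    """Final aging pattern: voxels surviving the filter in all M folds,
    ranked by mean fold weight (descending, ties by ascending index)."""

    voxels: np.ndarray
    mean_weight: np.ndarray
    fold_presence: np.ndarray
    M: int

    def __len__(self) -> int:
        return len(self.voxels)


def _select_in_fold(
    train: Cohort, params: PipelineParams, fold_id: int = 0
) -> tuple[RankedVoxels, BatchWeighting]:
    """Voxel selection on training subjects only: t filter then recursion."""
    t = voxelwise_tscore(train)
    k = min(params.filter_k, train.n_voxels)
    filtered = filter_top_k(t, k, by_abs=params.rank_by_abs_t)
    weighting = recursive_select(
        train.X[:, filtered.order],
        train.labels.astype(float),
        tscores=filtered.scores,
        batch_size=params.batch_size,
        round_size=params.round_size,
        n_solves=params.n_solves,
        subsample_fraction=params.subsample_fraction,
        seed=(params.seed * 100_003 + 7_919 * fold_id) % 2**31,
        max_rounds=params.max_rounds,
    )
    # map column positions of the filtered matrix back to flat voxel indices
    weighting = BatchWeighting(
        order=filtered.order[weighting.order],
        weights=weighting.weights,
        batch_size=weighting.batch_size,
        rounds=weighting.rounds,
    )
    return filtered, weighting


def run_fold(cohort: Cohort, plan: FoldPlan, fold_id: int, params: PipelineParams) -> FoldResult:
    """One CV fold: in-fold selection, training, held-out scoring."""
    train = cohort.subset(plan.train_indices(fold_id))
    test_idx = plan.test_indices(fold_id)
    test = cohort.subset(test_idx)

    filtered, weighting = _select_in_fold(train, params, fold_id)
    n_classify = min(params.n_classify, len(weighting.order))
    use = weighting.order[:n_classify]

    model = train_margin_classifier(train.X[:, use], train.labels, C=params.C)
    scores = model.decision_scores(test.X[:, use])
    pred = np.where(scores >= 0, 1, -1)
    metrics = confusion_and_metrics(test.labels, pred)
    return FoldResult(
        fold_id=fold_id,
        filtered=filtered,
        weighting=weighting,
        metrics=metrics,
        test_indices=test_idx,
        test_scores=scores,
        test_pred=pred,
    )


def consensus_pattern(
    fold_weightings: list[BatchWeighting], top_n: int = DEFAULT_PATTERN_SIZE
) -> ConsensusPattern:
    """Intersect the per-fold voxel sets and rank by mean fold weight."""
    if len(fold_weightings) < 2:
        raise ValueError("need weightings from at least 2 folds")
    M = len(fold_weightings)
    maps = [bw.weight_of() for bw in fold_weightings]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    if not common:
        warnings.warn("empty intersection across folds; consensus pattern is empty",
                      stacklevel=2)
        empty = np.array([], dtype=int)
        return ConsensusPattern(voxels=empty, mean_weight=np.array([]),
                                fold_presence=empty.copy(), M=M)
    voxels = np.array(sorted(common), dtype=int)
    mean_w = np.array([np.mean([m[v] for m in maps]) for v in voxels])
    order = np.lexsort((voxels, -mean_w))
    voxels, mean_w = voxels[order], mean_w[order]
    if len(voxels) < top_n:
        warnings.warn(
            f"only {len(voxels)} voxels survive in all folds (requested {top_n})",
            stacklevel=2,
        )
    else:
        voxels, mean_w = voxels[:top_n], mean_w[:top_n]
    return ConsensusPattern(
        voxels=voxels,
        mean_weight=mean_w,
        fold_presence=np.full(len(voxels), M, dtype=int),
        M=M,
    )


@dataclass
class CVResult:
    plan: FoldPlan
    folds: list[FoldResult]
    pattern: ConsensusPattern
    params: PipelineParams

    @property
    def pooled_metrics(self) -> ConfusionMetrics:
        total = self.folds[0].metrics
        for f in self.folds[1:]:
            total = total + f.metrics
        return total

    @property
    def pooled_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """(subject order, decision scores) pooled over held-out folds."""
        idx = np.concatenate([f.test_indices for f in self.folds])
        sc = np.concatenate([f.test_scores for f in self.folds])
        order = np.argsort(idx)
        return idx[order], sc[order]


def run_cv(cohort: Cohort, params: PipelineParams) -> CVResult:
    """Full M-fold pipeline: per-fold selection + consensus pattern."""
    plan = make_folds(cohort.labels, params.folds, params.seed)
    folds = [run_fold(cohort, plan, m, params) for m in range(plan.M)]
    pattern = consensus_pattern([f.weighting for f in folds], params.pattern_size)
    return CVResult(plan=plan, folds=folds, pattern=pattern, params=params)


def loocv_metrics(
    cohort: Cohort, voxels: np.ndarray, C: float = 1.0
) -> tuple[ConfusionMetrics, np.ndarray]:
    """Leave-one-out CV of the margin classifier on a fixed voxel set."""
    voxels = np.asarray(voxels, dtype=int)
    n = cohort.n_subjects
    pred = np.empty(n, dtype=int)
    scores = np.empty(n)
    for i in range(n):
        train_rows = np.delete(np.arange(n), i)
        model = train_margin_classifier(
            cohort.X[np.ix_(train_rows, voxels)], cohort.labels[train_rows], C=C
        )
        s = model.decision_scores(cohort.X[i, voxels][None, :])[0]
        scores[i] = s
        pred[i] = 1 if s >= 0 else -1
    return confusion_and_metrics(cohort.labels, pred), scores


def apply_pattern(
    pattern: ConsensusPattern, cohort2: Cohort, C: float = 1.0
) -> tuple[ConfusionMetrics, np.ndarray]:
    """Validate a fixed pattern on a second cohort by LOOCV.

    The second cohort must live on the same voxel grid; classification is
    restricted to the pattern voxels.
    """
    if len(pattern) == 0:
        raise ValueError("cannot apply an empty consensus pattern")
    if pattern.voxels.max() >= cohort2.n_voxels:
        raise ValueError("pattern voxels are not resolvable in the second cohort's mask")
    return loocv_metrics(cohort2, pattern.voxels, C=C)


def accuracy_vs_nvoxels(
    cohort: Cohort,
    n_grid: list[int],
    params: PipelineParams,
    method: str = "sparse",
) -> list[tuple[int, float]]:
    """Cross-validated GR as a function of the number of top-ranked voxels.

    The ranking (sparse batch order or plain |t| order, per ``method``) is
    recomputed inside each training fold; for each n in ``n_grid`` the
    classifier uses the first n ranked voxels of that fold.
    """
    if method not in ("sparse", "ttest"):
        raise ValueError("method must be 'sparse' or 'ttest'")
    plan = make_folds(cohort.labels, params.folds, params.seed)
    fold_orders: list[np.ndarray] = []
    fold_rows: list[tuple[np.ndarray, np.ndarray]] = []
    for m in range(plan.M):
        train = cohort.subset(plan.train_indices(m))
        if method == "sparse":
            _, weighting = _select_in_fold(train, params, m)
            fold_orders.append(weighting.order)
        else:
            t = voxelwise_tscore(train)
            k = min(params.filter_k, train.n_voxels)
            fold_orders.append(filter_top_k(t, k, by_abs=params.rank_by_abs_t).order)
        fold_rows.append((plan.train_indices(m), plan.test_indices(m)))

    curve = []
    for n_vox in n_grid:
        if any(n_vox > len(o) for o in fold_orders):
            raise ValueError(f"n={n_vox} exceeds the in-fold ranking length")
        total: ConfusionMetrics | None = None
        for order, (train_rows, test_rows) in zip(fold_orders, fold_rows):
            use = order[:n_vox]
            model = train_margin_classifier(
                cohort.X[np.ix_(train_rows, use)], cohort.labels[train_rows],
                C=params.C,
            )
            pred = model.predict(cohort.X[np.ix_(test_rows, use)])
            cm = confusion_and_metrics(cohort.labels[test_rows], pred)
            total = cm if total is None else total + cm
        curve.append((n_vox, total.GR))
    return curve
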