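"""Recursive L1-minimisation voxel selection by linear programming.

The multivariate selection step treats the label vector y (+1 young,
-1 old) as a sparse linear combination of voxel columns: find w minimising
||w||_1 subject to A w = y, where A is the (standardised) subject-by-voxel
matrix.  The 1-norm objective is the linear-programming relaxation of the
combinatorial sparsest-solution problem; with the split w = u - v,
u, v >= 0, it becomes a standard non-negative LP

    min sum(u + v)  s.t.  [A, -A] [u; v] = y,  u, v >= 0,

solved here with HiGHS.

A basic solution supports at most as many columns as there are subjects,
and when informative voxels are mutually redundant (whole clusters carrying
the same signal) a single solve keeps only a few interchangeable
representatives per cluster — it cannot reflect the importance of each
voxel.  The recursive selection therefore scores voxels with the LP's dual
certificate: at optimality every support column satisfies |a_j' lambda| = 1
and any column interchangeable with the support scores close to 1, so the
mean of |a_j' lambda| over a few LPs solved on balanced subject resamples
is a dense importance measure.  Each round selects the ``round_size``
(default 200) highest-scoring remaining voxels and removes them before the
next round;
the resulting order is weighted by the descending batch ladder — batches of
200 from a 20,000-voxel filter give weights 1.00, 0.99, ..., 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "SparseSolution",
    "BatchWeighting",
    "solve_min_l1",
    "recursive_select",
    "assign_batch_weights",
    "standardize_columns",
    "DEFAULT_BATCH_SIZE",
]

DEFAULT_BATCH_SIZE = 200

#: max allowed ||Aw - y||_inf for a solution to count as feasible
FEASIBILITY_TOL = 1e-7
#: |w_j| above this belongs to the support
SUPPORT_TOL = 1e-8


@dataclass
class SparseSolution:
    """Solution of one min-||w||_1 subject to Aw = y problem.

    ``dual`` carries the multipliers of the equality constraints; the
    per-column certificate |a_j' dual| equals 1 on the support and measures
    how close every other column is to being selected.
    """

    status: str  # "optimal" | "infeasible"
    w: np.ndarray | None
    l1_norm: float = math.nan
    residual_inf: float = math.nan
    support: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    dual: np.ndarray | None = None

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


def solve_min_l1(
    A: np.ndarray,
    y: np.ndarray,
    support_tol: float = SUPPORT_TOL,
    feasibility_tol: float = FEASIBILITY_TOL,
) -> SparseSolution:
    """Minimum-1-norm solution of the underdetermined system A w = y.

    Returns an explicit ``infeasible`` status when the equality system has
    no solution; raises only on solver failure.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ValueError(f"A must be a 2-D matrix, got shape {A.shape}")
    if y.shape != (A.shape[0],):
        raise ValueError("y length must equal the number of rows of A")

    m = A.shape[1]
    res = linprog(
        c=np.ones(2 * m),
        A_eq=np.hstack([A, -A]),
        b_eq=y,
        bounds=(0, None),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return SparseSolution(status="infeasible", w=None)
    if not res.success:
        raise RuntimeError(f"LP solver failed (status {res.status}): {res.message}")

    w = res.x[:m] - res.x[m:]
    resid = float(np.max(np.abs(A @ w - y))) if len(y) else 0.0
    if resid > feasibility_tol:
        # solver declared success but the equality is not met to tolerance
        return SparseSolution(status="infeasible", w=w, residual_inf=resid)
    support = np.flatnonzero(np.abs(w) > support_tol)
    dual = res.eqlin.marginals if hasattr(res, "eqlin") else None
    return SparseSolution(
        status="optimal",
        w=w,
        l1_norm=float(np.sum(np.abs(w))),
        residual_inf=resid,
        support=support,
        dual=None if dual is None else np.asarray(dual, dtype=float),
    )


@dataclass
class BatchWeighting:
    """Global selection order with the descending batch-weight ladder.

    Batch b (1-based) of ``batch_size`` consecutive voxels gets weight
    (B - b + 1) / B where B is the number of batches; the last batch may be
    short.  ``rounds`` logs the LP support size of each recursion round
    (-1 marks the univariate fallback tail).
    """

    order: np.ndarray
    weights: np.ndarray
    batch_size: int
    rounds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.order.shape != self.weights.shape:
            raise ValueError("order and weights must be aligned")

    @property
    def n_batches(self) -> int:
        return math.ceil(len(self.order) / self.batch_size)

    def weight_of(self) -> dict[int, float]:
        return dict(zip(self.order.tolist(), self.weights.tolist()))


def assign_batch_weights(order: np.ndarray, batch_size: int) -> BatchWeighting:
    """Convert a selection order into the descending batch-weight ladder."""
    order = np.asarray(order, dtype=int)
    if order.size == 0:
        raise ValueError("order must be non-empty")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    n_batches = math.ceil(order.size / batch_size)
    batch = np.arange(order.size) // batch_size  # 0-based
    weights = (n_batches - batch) / n_batches
    return BatchWeighting(order=order, weights=weights, batch_size=batch_size)


def standardize_columns(
    X: np.ndarray, mean: np.ndarray | None = None, sd: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-mean/unit-variance columns; constant columns become all-zero.

    Returns (standardised X, mean, sd) so that test data can be transformed
    with training statistics.
    """
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if sd is None:
        sd = X.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / safe
    Xs[:, sd == 0] = 0.0
    return Xs, mean, sd


def _balanced_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Row subset with round(fraction * class size) subjects per class
    (at least 2 each)."""
    rows = []
    for cls in (1, -1):
        members = np.flatnonzero(y == cls)
        take = max(2, int(round(fraction * members.size)))
        take = min(take, members.size)
        rows.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(rows))


def recursive_select(
    X: np.ndarray,
    y: np.ndarray,
    tscores: np.ndarray | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
    round_size: int = 200,
    n_solves: int = 2,
    subsample_fraction: float = 0.45,
    seed: int = 0,
    standardize: bool = True,
    max_rounds: int | None = None,
) -> BatchWeighting:
    """Order all columns of X by recursive sparse selection.

    Each round solves the min-L1 problem ``n_solves`` times on balanced
    subject resamples of the remaining columns and scores every remaining
    column by the mean dual certificate |a_j' lambda|; the ``round_size``
    highest-scoring columns are appended to the global order (ties by
    ascending column index) and removed.  When the system becomes
    infeasible, the remaining column count drops below the subsample row
    count, or ``max_rounds`` is reached, the remaining columns are appended
    in decreasing |t| order (``tscores``; zeros if not given).  The order is
    then converted to batch weights (one weight step per ``batch_size``
    positions, independent of the round size).

    Columns are standardised per subsample and the subsample's label mean is
    subtracted from y, which keeps the equality system feasible for
    unbalanced class counts.  Fully deterministic for a fixed ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, v = X.shape
    if v < batch_size:
        raise ValueError(f"need at least batch_size={batch_size} columns, got {v}")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if n_solves < 1:
        raise ValueError("n_solves must be >= 1")
    if round_size < 1:
        raise ValueError("round_size must be >= 1")
    if tscores is None:
        tscores = np.zeros(v)
    tscores = np.asarray(tscores, dtype=float)
    rng = np.random.default_rng(seed)

    remaining = np.arange(v)
    order: list[np.ndarray] = []
    rounds: list[int] = []
    n_rounds = 0
    lp_alive = True
    while lp_alive and remaining.size > 0 and (
        max_rounds is None or n_rounds < max_rounds
    ):
        importance = np.zeros(remaining.size)
        used = 0
        for _ in range(n_solves):
            rows = _balanced_subsample(y, subsample_fraction, rng)
            if remaining.size < rows.size:
                break  # exact fit would be overdetermined
            Xr = X[np.ix_(rows, remaining)]
            if standardize:
                Xr, _, _ = standardize_columns(Xr)
            yr = y[rows] - y[rows].mean()
            sol = solve_min_l1(Xr, yr)
            if not sol.feasible or sol.dual is None:
                continue
            importance += np.abs(Xr.T @ sol.dual)
            used += 1
        if used == 0:
            lp_alive = False
            break
        take = min(round_size, remaining.size)
        picked_local = np.lexsort((remaining, -importance))[:take]
        order.append(remaining[picked_local])
        rounds.append(int(take))
        keep = np.ones(remaining.size, dtype=bool)
        keep[picked_local] = False
        remaining = remaining[keep]
        n_rounds += 1

    if remaining.size:
        tail = remaining[np.lexsort((remaining, -np.abs(tscores[remaining])))]
        order.append(tail)
        rounds.append(-1)

    full_order = np.concatenate(order)
    weighting = assign_batch_weights(full_order, batch_size)
    weighting.rounds = rounds
    return weighting
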