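"""Max-margin classification and the GR/SS/SC accuracy metrics.

Young subjects are the positive class everywhere.  Rates follow the usual
confusion-matrix definitions: generalization rate GR = (TP+TN)/N (overall
accuracy), sensitivity SS = TP/(TP+FN) (correctly predicted young) and
specificity SC = TN/(TN+FP) (correctly predicted old).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
from sklearn.svm import SVC

from .sparse import standardize_columns

__all__ = [
    "ConfusionMetrics",
    "MarginModel",
    "train_margin_classifier",
    "confusion_and_metrics",
    "score_age_correlation",
    "percent",
]


def percent(fraction: float, decimals: int = 1) -> float:
    """Format a fraction as a percentage, round-half-to-even."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived rates (young = positive class)."""

    TP: int  # young predicted young
    FN: int  # young predicted old
    TN: int  # old predicted old
    FP: int  # old predicted young

    @property
    def n(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    @property
    def GR(self) -> float:
        return (self.TP + self.TN) / self.n

    @property
    def SS(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def SC(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def GR_percent(self) -> float:
        return percent(self.GR)

    @property
    def SS_percent(self) -> float:
        return percent(self.SS)

    @property
    def SC_percent(self) -> float:
        return percent(self.SC)

    def __add__(self, other: "ConfusionMetrics") -> "ConfusionMetrics":
        return ConfusionMetrics(
            self.TP + other.TP, self.FN + other.FN,
            self.TN + other.TN, self.FP + other.FP,
        )

    def __str__(self) -> str:
        return (
            f"GR: {self.GR_percent}%, SS: {self.SS_percent}%, SC: {self.SC_percent}% "
            f"(TP={self.TP}, FN={self.FN}, TN={self.TN}, FP={self.FP})"
        )


def confusion_and_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMetrics:
    """Confusion counts from true and predicted +/-1 labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.all(np.isin(arr, (1, -1))):
            raise ValueError(f"{name} must contain only +1/-1")
    return ConfusionMetrics(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
    )


@dataclass
class MarginModel:
    """Fitted soft-margin linear classifier with its training scaler.

    The decision score is w.x_standardised + b; the prediction is its sign
    (ties at exactly 0 go to the young class).
    """

    weights: np.ndarray
    bias: float
    C: float
    train_mean: np.ndarray
    train_sd: np.ndarray

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Xs, _, _ = standardize_columns(X, self.train_mean, self.train_sd)
        return Xs @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_scores(X)
        return np.where(s >= 0, 1, -1)


def train_margin_classifier(
    X_train: np.ndarray, y_train: np.ndarray, C: float = 1.0,
) -> MarginModel:
    """Train a soft-margin linear SVM on standardised training features."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    Xs, mean, sd = standardize_columns(X_train)
    svm = SVC(kernel="linear", C=C, tol=1e-8)
    svm.fit(Xs, y_train)
    return MarginModel(
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        C=C,
        train_mean=mean,
        train_sd=sd,
    )


def score_age_correlation(scores: np.ndarray, ages: np.ndarray) -> float:
    """Pearson correlation between classifier decision scores and age."""
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if scores.size < 3 or scores.shape != ages.shape:
        raise ValueError("need >= 3 aligned (score, age) pairs")
    if np.std(scores) == 0 or np.std(ages) == 0:
        raise ValueError("zero variance in scores or ages")
    return float(np.corrcoef(scores, ages)[0, 1])
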