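"""Per-tissue accuracy, overall accuracy and the multiclass Matthews
correlation coefficient (MCC).

With ``n`` samples and ``N`` classes, truth and prediction are encoded as
0/1 indicator matrices ``Y`` and ``X`` (one row per sample summing to 1).
Per-class accuracy is ``ACC_j = n_j / N_j`` (correct over total in class j),
overall accuracy ``TACC = Σ n_j / Σ N_j``, and the multiclass MCC is
Gorodkin's normalized covariance

    MCC = cov(X, Y) / sqrt(cov(X, X) · cov(Y, Y)),

where ``cov(X, Y) = (1/N) Σ_k Σ_i (x_ik − x̄_k)(y_ik − ȳ_k)`` averages the
column-wise centered covariances.  MCC lies in [−1, 1]: 1 for a perfect
classifier, 0 for one no better than random, −1 for total (binary)
misclassification.  When a covariance denominator is exactly 0 — a constant
prediction or a single represented class — MCC is defined as 0 here, since
such a classifier is no better than random; the choice is pinned by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "IndicatorPair",
    "CVResult",
    "indicator_matrix",
    "per_class_accuracy",
    "overall_accuracy",
    "multiclass_mcc",
    "confusion_from_labels",
]


@dataclass
class IndicatorPair:
    """Truth (``Y``) and prediction (``X``) 0/1 indicator matrices, n × N."""

    Y: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        self.X = np.asarray(self.X)
        if self.Y.shape != self.X.shape or self.Y.ndim != 2:
            raise ValidationError(
                f"X and Y must share an n×N shape, got {self.X.shape} vs {self.Y.shape}"
            )
        for name, M in (("Y", self.Y), ("X", self.X)):
            if not np.isin(M, (0, 1)).all():
                raise ValidationError(f"{name} must contain only 0/1 entries")
            if not (M.sum(axis=1) == 1).all():
                raise ValidationError(f"every row of {name} must sum to exactly 1")

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_classes(self) -> int:
        return self.Y.shape[1]


@dataclass
class CVResult:
    """Pooled evaluation result: confusion counts and the accuracy suite.

    ``confusion[j, l]`` counts samples of true class j predicted as class l
    (classes in ``tags`` order).  Satisfies ``n_j ≤ N_j``,
    ``Σ confusion = Σ N_j`` and ``tacc = Σ n_j / Σ N_j``.
    """

    tags: list[str]
    confusion: np.ndarray
    per_class_n: np.ndarray
    per_class_N: np.ndarray
    acc: np.ndarray
    tacc: float
    mcc: float

    def to_frame(self) -> pd.DataFrame:
        """Per-tissue report rows plus TACC and MCC footer rows."""
        rows = [
            {"tissue": t, "n_correct": int(n), "n_total": int(N), "value": a}
            for t, n, N, a in zip(self.tags, self.per_class_n, self.per_class_N, self.acc)
        ]
        rows.append({"tissue": "TACC", "n_correct": int(self.per_class_n.sum()),
                     "n_total": int(self.per_class_N.sum()), "value": self.tacc})
        rows.append({"tissue": "MCC", "n_correct": "", "n_total": "", "value": self.mcc})
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def indicator_matrix(labels, tag_order: list[str]) -> np.ndarray:
    """Encode a label vector as an n × N 0/1 matrix in ``tag_order``."""
    index = {t: j for j, t in enumerate(tag_order)}
    n = len(labels)
    M = np.zeros((n, len(tag_order)), dtype=np.int64)
    for i, lab in enumerate(labels):
        try:
            M[i, index[lab]] = 1
        except KeyError:
            raise ValidationError(f"label {lab!r} not in tag order") from None
    return M


def per_class_accuracy(pair: IndicatorPair) -> np.ndarray:
    """ACC_j = n_j / N_j for every class; a class with N_j = 0 is an error."""
    n_j = (pair.X * pair.Y).sum(axis=0)
    N_j = pair.Y.sum(axis=0)
    empty = np.flatnonzero(N_j == 0)
    if empty.size:
        raise ValidationError(f"class index {empty[0]} has no true samples (N_j = 0)")
    return n_j / N_j


def overall_accuracy(pair: IndicatorPair) -> float:
    """TACC: total correct over total samples."""
    n_correct = int((pair.X * pair.Y).sum())
    return n_correct / pair.n_samples


def multiclass_mcc(pair: IndicatorPair) -> float:
    """Gorodkin's multiclass MCC from the indicator pair.

    The common 1/N factor of the covariance average cancels in the ratio but
    is applied anyway so the intermediate covariances match their definition.
    """
    if pair.n_classes < 2:
        raise ValidationError("multiclass MCC requires N >= 2 classes")
    X = pair.X.astype(float)
    Y = pair.Y.astype(float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    N = pair.n_classes
    cov_xy = (Xc * Yc).sum() / N
    cov_xx = (Xc * Xc).sum() / N
    cov_yy = (Yc * Yc).sum() / N
    denom = np.sqrt(cov_xx * cov_yy)
    if denom == 0.0:
        return 0.0
    return float(cov_xy / denom)


def confusion_from_labels(
    true_labels, predicted_labels, tag_order: list[str]
) -> tuple[IndicatorPair, CVResult]:
    """Build the indicator pair and a fully populated :class:`CVResult`.

    ``tag_order`` fixes the class axis; it is never inferred or sorted.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("true and predicted label vectors differ in length")
    Y = indicator_matrix(true_labels, tag_order)
    X = indicator_matrix(predicted_labels, tag_order)
    pair = IndicatorPair(Y=Y, X=X)
    confusion = Y.T @ X  # [true, predicted]
    per_class_N = confusion.sum(axis=1)
    per_class_n = np.diag(confusion).copy()
    acc = per_class_accuracy(pair)
    result = CVResult(
        tags=list(tag_order),
        confusion=confusion,
        per_class_n=per_class_n,
        per_class_N=per_class_N,
        acc=acc,
        tacc=overall_accuracy(pair),
        mcc=multiclass_mcc(pair),
    )
    return pair, result
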