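"""Multi-class SVM training and the 10-fold cross-validation harness.

The classifier mirrors the defaults of the classic SMO implementation in
Weka: a polynomial kernel of degree 1 (i.e. K(u, v) = ⟨u, v⟩), C = 1,
convergence tolerance 0.001, per-feature min–max normalization to [0, 1]
fitted on training data only, and one-vs-one multiclass decomposition with
majority voting.  The quadratic-programming solver itself is delegated to
scikit-learn's ``SVC``; what is bespoke here is the surrounding contract —
feature subsetting, train-only normalization, deterministic behavior, and a
single stratified fold partition reused across every feature set so that
differences along the feature-selection curve reflect features rather than
fold noise.

Expression values are passed through log2(x + 1) before normalization by
default: RPKM-scale data are strongly right-skewed, and under a min–max
scaler a degree-1 kernel is otherwise dominated by the extreme upper tail.
Set ``log2_transform=False`` to model raw RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, MinMaxScaler
from sklearn.svm import SVC

from .errors import ValidationError
from .io import ExpressionMatrix, SampleLabels
from .metrics import CVResult, confusion_from_labels

__all__ = ["SVMParams", "FeatureSet", "train_svm", "make_folds", "cross_validate"]


@dataclass
class SVMParams:
    """Hyper-parameters of the SMO-style polynomial-kernel SVM."""

    degree: int = 1
    C: float = 1.0
    tolerance: float = 0.001
    log2_transform: bool = True

    kernel: str = "poly"  # the only supported kernel family

    def __post_init__(self) -> None:
        if self.kernel != "poly":
            raise ValidationError("only the polynomial kernel is supported")
        if self.degree < 1 or self.C <= 0 or self.tolerance <= 0:
            raise ValidationError("degree >= 1, C > 0 and tolerance > 0 required")


@dataclass
class FeatureSet:
    """An ordered gene-id list, typically a prefix of a ranked feature list."""

    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError("feature set must contain at least one gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("feature set contains duplicate gene ids")

    @property
    def i(self) -> int:
        return len(self.gene_ids)


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(x + 1.0)


def _design_matrix(matrix: ExpressionMatrix, feature_set: FeatureSet) -> np.ndarray:
    """Samples × features design matrix restricted to the feature set."""
    return matrix.subset_genes(feature_set.gene_ids).data.to_numpy(dtype=float).T


def _make_pipeline(params: SVMParams) -> Pipeline:
    steps = []
    if params.log2_transform:
        steps.append(("log2", FunctionTransformer(_log2p1, validate=False)))
    steps.append(("scale", MinMaxScaler(clip=False)))
    steps.append(
        (
            "svm",
            SVC(
                kernel="poly",
                degree=params.degree,
                gamma=1.0,
                coef0=0.0,
                C=params.C,
                tol=params.tolerance,
                cache_size=200,
            ),
        )
    )
    return Pipeline(steps)


def train_svm(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    feature_set: FeatureSet,
    params: SVMParams | None = None,
) -> Pipeline:
    """Fit the SVM pipeline on all samples of ``matrix``.

    Normalization statistics are part of the returned pipeline, so applying
    it to new samples reuses the training min–max range.  Training is
    deterministic for fixed inputs.
    """
    params = params or SVMParams()
    y = labels.for_samples(matrix.sample_ids)
    if len(np.unique(y)) < 2:
        raise ValidationError("training requires at least two tissue classes")
    model = _make_pipeline(params)
    model.fit(_design_matrix(matrix, feature_set), y)
    return model


def predict(model: Pipeline, matrix: ExpressionMatrix, feature_set: FeatureSet) -> np.ndarray:
    """Predict one tissue tag per sample of ``matrix``."""
    return model.predict(_design_matrix(matrix, feature_set))


def make_folds(
    labels: SampleLabels, sample_ids: list[str], k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """A stratified k-fold partition of ``sample_ids``, fixed by ``seed``.

    Generate once per pipeline run and pass to every :func:`cross_validate`
    call so all feature sets are scored on identical folds.
    """
    if k < 2:
        raise ValidationError("k-fold cross-validation requires k >= 2")
    y = labels.for_samples(sample_ids)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train_idx, test_idx)
        for train_idx, test_idx in splitter.split(np.zeros(len(y)), y)
    ]


def cross_validate(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    feature_set: FeatureSet,
    k: int = 10,
    seed: int = 0,
    params: SVMParams | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the SVM on one feature set.

    The normalizer is refitted inside each training fold (no test-fold
    leakage); out-of-fold predictions are pooled into a single
    :class:`~tissueclf.metrics.CVResult` in the labels' tissue order.
    """
    params = params or SVMParams()
    sample_ids = matrix.sample_ids
    y = labels.for_samples(sample_ids)
    if folds is None:
        folds = make_folds(labels, sample_ids, k=k, seed=seed)
    X = _design_matrix(matrix, feature_set)
    predicted = np.empty(len(y), dtype=object)
    seen = np.zeros(len(y), dtype=bool)
    for train_idx, test_idx in folds:
        model = _make_pipeline(params)
        model.fit(X[train_idx], y[train_idx])
        predicted[test_idx] = model.predict(X[test_idx])
        seen[test_idx] = True
    if not seen.all():
        raise ValidationError("fold partition does not cover every sample")
    tag_order = [t for t in labels.tissues if t in set(y)]
    _, result = confusion_from_labels(y, predicted, tag_order)
    return result
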