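"""Minimum-redundancy maximum-relevance (mRMR) gene ranking.

Continuous expression is first discretized gene-by-gene into three states
using the classic mean ± α·σ rule (state −1 below μ − ασ, +1 above μ + ασ,
0 between; α = 1 by default).  Mutual information between discrete variables
is the plug-in estimate over empirical joint frequencies, in bits (log base
2); the base cancels in rankings but is pinned for reproducible scores.

The ranking is the standard greedy: the first gene maximizes relevance
MI(f; c) with the tissue label c treated as one categorical variable; each
later gene maximizes, over the non-selected genes,

    MID:  MI(f; c) − mean_{s ∈ S} MI(f; s)        (difference form, default)
    MIQ:  MI(f; c) / mean_{s ∈ S} MI(f; s)        (quotient form)

where S is the already-selected set.  Ties are broken by input gene order,
and every pairwise MI is computed at most once (each gene's MI against all
remaining candidates is evaluated exactly when it is selected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, SampleLabels

__all__ = [
    "DiscretizedMatrix",
    "RankedFeatureList",
    "discretize_expression",
    "mutual_information",
    "rank_features_mrmr",
    "write_ranked_list",
    "read_ranked_list",
]

_STATES = (-1, 0, 1)
_MIQ_EPS = 1e-12  # keeps the quotient defined when mean redundancy is 0


@dataclass
class DiscretizedMatrix:
    """Three-state (−1/0/+1) discretization of an expression matrix with the
    per-gene (low, high) cut values that produced it."""

    gene_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray  # int8, genes × samples
    thresholds: np.ndarray  # float, genes × 2 (low, high)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, _STATES).all():
            raise ValidationError("states must come from the alphabet {-1, 0, +1}")
        if self.states.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("state matrix shape inconsistent with identifiers")
        if (self.thresholds[:, 0] > self.thresholds[:, 1]).any():
            raise ValidationError("thresholds must satisfy low <= high")


@dataclass
class RankedFeatureList:
    """Genes ordered by selection, with the score each had when selected."""

    gene_ids: list[str]
    scores: np.ndarray
    criterion: str

    def top(self, i: int) -> list[str]:
        if i > len(self.gene_ids):
            raise ValidationError(
                f"requested top {i} of a {len(self.gene_ids)}-gene list"
            )
        return self.gene_ids[:i]


def discretize_expression(matrix: ExpressionMatrix, alpha: float = 1.0) -> DiscretizedMatrix:
    """Discretize each gene at mean ± alpha·SD (population SD, ddof 0).

    A constant gene has σ = 0 and maps entirely to state 0.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be > 0")
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValidationError("cannot discretize an empty matrix")
    values = matrix.data.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sigma = values.std(axis=1, keepdims=True)
    low = mu - alpha * sigma
    high = mu + alpha * sigma
    states = np.zeros(values.shape, dtype=np.int8)
    states[values < low] = -1
    states[values > high] = 1
    return DiscretizedMatrix(
        gene_ids=matrix.gene_ids,
        sample_ids=matrix.sample_ids,
        states=states,
        thresholds=np.hstack([low, high]),
    )


def _encode(seq) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(seq), use_na_sentinel=False)
    return codes.astype(np.int64), len(uniques)


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI in bits from a 2-D contingency table of counts."""
    total = joint.sum()
    if total == 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / (px @ py)[mask])).sum())


def mutual_information(x, y) -> float:
    """MI(x; y) in bits between two equal-length discrete sequences.

    Non-negative and symmetric; 0·log 0 terms contribute nothing.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    if x.size == 0:
        raise ValidationError("sequences must be non-empty")
    cx, kx = _encode(x)
    cy, ky = _encode(y)
    joint = np.zeros((kx, ky), dtype=np.int64)
    np.add.at(joint, (cx, cy), 1)
    return _mi_from_joint(joint)


def _mi_rows_vs(codes: np.ndarray, n_row_states: int, y: np.ndarray, ky: int) -> np.ndarray:
    """MI of every row of ``codes`` (values in 0..n_row_states-1) against the
    shared code vector ``y`` — vectorized over rows."""
    n_genes, n = codes.shape
    joint = np.empty((n_genes, n_row_states, ky), dtype=np.float64)
    for s in range(n_row_states):
        is_s = codes == s
        for k in range(ky):
            joint[:, s, k] = is_s[:, y == k].sum(axis=1)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return np.nansum(terms, axis=(1, 2))


def rank_features_mrmr(
    disc: DiscretizedMatrix,
    labels: SampleLabels,
    criterion: str = "MID",
    top_n: int | None = None,
) -> RankedFeatureList:
    """Greedy mRMR ranking of all genes (or the first ``top_n``).

    Raises if the samples carry a single tissue only: relevance to a constant
    target is not a discrimination problem.
    """
    criterion = criterion.upper()
    if criterion not in ("MID", "MIQ"):
        raise ValidationError(f"criterion must be MID or MIQ, got {criterion!r}")
    n_genes = len(disc.gene_ids)
    if n_genes == 0:
        raise ValidationError("no genes to rank")
    tags = labels.for_samples(disc.sample_ids)
    y, ky = _encode(tags)
    if ky < 2:
        raise ValidationError("mRMR ranking needs at least two tissue classes")
    if top_n is None:
        top_n = n_genes
    top_n = min(top_n, n_genes)

    codes = (disc.states + 1).astype(np.int64)  # {-1,0,1} -> {0,1,2}
    relevance = _mi_rows_vs(codes, 3, y, ky)

    selected: list[int] = []
    scores: list[float] = []
    remaining = np.ones(n_genes, dtype=bool)
    redundancy_sum = np.zeros(n_genes, dtype=float)

    first = int(np.argmax(relevance))  # argmax takes the first max: input-order ties
    selected.append(first)
    scores.append(float(relevance[first]))
    remaining[first] = False

    while len(selected) < top_n:
        last = selected[-1]
        # one pass of pairwise MI against the gene just selected, restricted
        # to still-candidate genes, so no pair is ever evaluated twice
        cand = np.flatnonzero(remaining)
        redundancy_sum[cand] += _mi_rows_vs(codes[cand], 3, codes[last], 3)
        mean_red = redundancy_sum / len(selected)
        if criterion == "MID":
            score = relevance - mean_red
        else:
            score = relevance / np.maximum(mean_red, _MIQ_EPS)
        score = np.where(remaining, score, -np.inf)
        pick = int(np.argmax(score))
        selected.append(pick)
        scores.append(float(score[pick]))
        remaining[pick] = False

    return RankedFeatureList(
        gene_ids=[disc.gene_ids[i] for i in selected],
        scores=np.array(scores),
        criterion=criterion,
    )


def write_ranked_list(ranked: RankedFeatureList, path) -> None:
    pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked.gene_ids) + 1),
            "gene_id": ranked.gene_ids,
            "score": ranked.scores,
            "criterion": ranked.criterion,
        }
    ).to_csv(path, sep="\t", index=False)


def read_ranked_list(path) -> RankedFeatureList:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    expected = ["rank", "gene_id", "score", "criterion"]
    if list(df.columns) != expected:
        raise ValidationError(f"ranked list must have columns {expected}")
    return RankedFeatureList(
        gene_ids=list(df["gene_id"]),
        scores=df["score"].to_numpy(),
        criterion=str(df["criterion"].iloc[0]) if len(df) else "MID",
    )
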