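"""Incremental feature selection (IFS): score growing prefixes of a ranked
gene list by cross-validation and pick the best one.

Given a ranked list F = [f1, f2, …, fN], the prefix F_i = [f1, …, fi] is
evaluated for every i in the scan range (default 4–500, the range used with
18k-gene expression panels; a ``step`` > 1 coarsens the scan for speed).
The optimal model is the point with the highest multiclass MCC; ties go to
the smallest i (parsimony).  All points share one stratified fold partition,
so the curve reflects the features and not fold resampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import FeatureSet, SVMParams, cross_validate, make_folds
from .errors import ValidationError
from .io import ExpressionMatrix, SampleLabels
from .metrics import CVResult
from .mrmr import RankedFeatureList

__all__ = ["IFSCurve", "run_ifs", "select_optimal", "write_curve", "read_curve", "plot_curve"]


@dataclass
class IFSCurve:
    """Sequence of (feature count, pooled CV result) points, i increasing."""

    points: list[tuple[int, CVResult]]
    scan_range: tuple[int, int, int]  # (i_min, i_max, step)
    ranked_genes: list[str] | None = None  # head of the ranked list, for prefixes

    def __post_init__(self) -> None:
        sizes = [i for i, _ in self.points]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError("curve points must have strictly increasing i")

    @property
    def sizes(self) -> list[int]:
        return [i for i, _ in self.points]

    @property
    def mccs(self) -> np.ndarray:
        return np.array([r.mcc for _, r in self.points])


def run_ifs(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    ranked: RankedFeatureList,
    i_min: int = 4,
    i_max: int = 500,
    step: int = 1,
    k: int = 10,
    params: SVMParams | None = None,
    seed: int = 0,
) -> IFSCurve:
    """Cross-validate the SVM on every prefix F_i for i in the scan range."""
    if i_min < 1 or step < 1:
        raise ValidationError("i_min and step must be >= 1")
    if i_max > len(ranked.gene_ids):
        raise ValidationError(
            f"scan upper bound {i_max} exceeds ranked-list length {len(ranked.gene_ids)}"
        )
    if i_min > i_max:
        raise ValidationError("i_min must not exceed i_max")
    folds = make_folds(labels, matrix.sample_ids, k=k, seed=seed)
    points = []
    for i in range(i_min, i_max + 1, step):
        result = cross_validate(
            matrix, labels, FeatureSet(ranked.top(i)), params=params, folds=folds
        )
        points.append((i, result))
    return IFSCurve(
        points=points,
        scan_range=(i_min, i_max, step),
        ranked_genes=ranked.top(i_max),
    )


def select_optimal(curve: IFSCurve) -> tuple[int, FeatureSet | None, CVResult]:
    """The scan point with maximum MCC; ties broken by smallest i.

    The middle element is the optimal prefix as a :class:`FeatureSet` when the
    curve carries its ranked gene list (curves read back from TSV do not).
    """
    if not curve.points:
        raise ValidationError("cannot select from an empty curve")
    best = int(np.argmax(curve.mccs))  # first max -> smallest i on ties
    i, result = curve.points[best]
    features = FeatureSet(curve.ranked_genes[:i]) if curve.ranked_genes else None
    return i, features, result


def write_curve(curve: IFSCurve, path) -> None:
    """TSV of (i, MCC, TACC, per-tissue ACC columns)."""
    tags = curve.points[0][1].tags
    rows = []
    for i, r in curve.points:
        row = {"i": i, "MCC": r.mcc, "TACC": r.tacc}
        row.update({f"ACC_{t}": a for t, a in zip(r.tags, r.acc)})
        rows.append(row)
    pd.DataFrame(rows, columns=["i", "MCC", "TACC"] + [f"ACC_{t}" for t in tags]).to_csv(
        path, sep="\t", index=False
    )


def read_curve(path) -> pd.DataFrame:
    """Read a curve TSV back as a DataFrame (i, MCC, TACC, ACC_*)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["i", "MCC", "TACC"]:
        raise ValidationError("curve file must start with columns i, MCC, TACC")
    return df


def plot_curve(curve: IFSCurve, path) -> None:
    """Render the MCC-vs-feature-count curve with the optimum highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = curve.sizes
    mccs = curve.mccs
    best = int(np.argmax(mccs))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(sizes, mccs, lw=1.2, color="tab:blue")
    ax.plot(
        sizes[best],
        mccs[best],
        "D",
        color="tab:red",
        label=f"optimum: i={sizes[best]}, MCC={mccs[best]:.3f}",
    )
    ax.set_xlim(curve.scan_range[0], curve.scan_range[1])
    ax.set_xlabel("number of top-ranked genes")
    ax.set_ylabel("multiclass MCC (10-fold CV)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
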