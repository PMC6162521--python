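"""Comparison baselines: externally supplied gene lists and one-vs-rest
t-test marker selection.

``evaluate_gene_list`` scores an arbitrary gene panel (e.g. a curated
tissue-enriched list) with the same SVM/cross-validation harness as the main
pipeline, so its result is directly comparable to the feature-selection
optimum when the same fold seed is used.

The t-test route ranks genes per tissue by a Welch (unequal-variance)
two-sample t statistic of that tissue against all remaining samples; genes
with the largest positive t are the tissue's most over-expressed markers.
The union of each tissue's top-k markers (k = 19 by default, giving at most
19 × n_tissues unique genes) forms the t-test gene panel.  Welch's variant
is used because tissue group sizes are unequal; ranking is by t descending
(stable, so exact ties keep input gene order) with under-expressed genes
(t < 0) excluded, and p-values carried along for reporting only — the
selection is by rank, not by a significance threshold, so no multiplicity
correction applies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import FeatureSet, SVMParams, cross_validate
from .errors import ValidationError
from .io import ExpressionMatrix, SampleLabels
from .metrics import CVResult

__all__ = ["evaluate_gene_list", "ttest_rank_tissue", "select_ttest_genes"]


def evaluate_gene_list(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    gene_ids: list[str],
    params: SVMParams | None = None,
    k: int = 10,
    seed: int = 0,
    folds=None,
) -> CVResult:
    """Cross-validate the SVM restricted to ``gene_ids``.

    Genes absent from the matrix are reported via a warning and dropped;
    zero overlap is an error.  Passing the main run's ``folds`` (or the same
    seed) scores the list on the identical partition.
    """
    known = set(matrix.gene_ids)
    present = [g for g in gene_ids if g in known]
    missing = [g for g in gene_ids if g not in known]
    if not present:
        raise ValidationError("none of the listed genes are present in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} of {len(gene_ids)} listed genes are absent from the "
            f"matrix and were dropped: {missing[:10]}",
            stacklevel=2,
        )
    return cross_validate(
        matrix, labels, FeatureSet(present), k=k, seed=seed, params=params, folds=folds
    )


def ttest_rank_tissue(
    matrix: ExpressionMatrix, labels: SampleLabels, tissue_tag: str
) -> pd.DataFrame:
    """Rank all genes by Welch t of ``tissue_tag`` vs the rest, descending.

    Returns a DataFrame with columns gene_id, t, p_two_sided and
    p_over (one-sided, over-expression in the tissue); ties keep input
    gene order.
    """
    tags = labels.for_samples(matrix.sample_ids)
    in_group = tags == tissue_tag
    if tissue_tag not in labels.tissues:
        raise ValidationError(f"unknown tissue tag {tissue_tag!r}")
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValidationError(
            f"tissue {tissue_tag!r} needs >= 2 samples on each side of the test"
        )
    values = matrix.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(
            values[:, in_group], values[:, ~in_group], axis=1, equal_var=False
        )
    t = np.nan_to_num(res.statistic, nan=0.0)  # constant gene in both groups -> t = 0
    p_two = np.nan_to_num(res.pvalue, nan=1.0)
    # one-sided p for over-expression: halve on the correct tail
    p_over = np.where(t > 0, p_two / 2, 1 - p_two / 2)
    table = pd.DataFrame(
        {"gene_id": matrix.gene_ids, "t": t, "p_two_sided": p_two, "p_over": p_over}
    )
    return table.sort_values("t", ascending=False, kind="stable").reset_index(drop=True)


def select_ttest_genes(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    top_k: int = 19,
) -> tuple[list[str], dict[str, list[str]]]:
    """Union of each tissue's ``top_k`` over-expressed (t > 0) genes.

    Returns the unique gene list (ordered by first nomination) and a
    provenance map gene → tissues that nominated it.  The panel size lies
    in [top_k, top_k × n_tissues].
    """
    if len(labels.tissues) < 2:
        raise ValidationError("t-test selection needs at least two tissues")
    if top_k > matrix.n_genes:
        raise ValidationError(
            f"top_k={top_k} exceeds the {matrix.n_genes} genes available"
        )
    selected: list[str] = []
    provenance: dict[str, list[str]] = {}
    for tissue in labels.tissues:
        table = ttest_rank_tissue(matrix, labels, tissue)
        top = table.loc[table["t"] >= 0].head(top_k)["gene_id"]
        for gene in top:
            if gene not in provenance:
                selected.append(gene)
                provenance[gene] = []
            provenance[gene].append(tissue)
    return selected, provenance
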