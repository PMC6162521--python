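"""Expression-matrix and label I/O plus the dataset filtering rules.

The on-disk formats are the GCT v1.2 dialect shipped with GTEx RPKM releases
(version line ``#1.2``, a dimensions line, then ``Name``/``Description``
columns ahead of one column per sample) and a two-column TSV
(``SAMPID``/``SMTS``) for sample→tissue labels.

Two filters mirror standard preprocessing of the GTEx training set: genes are
kept only if expressed (strictly non-zero RPKM) in at least one sample, and
tissues with fewer than 80 samples are dropped.  "Non-zero" is literal
(``!= 0.0``): RPKM of exactly zero means no reads, anything else counts as
expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GCTParseError, ValidationError

GCT_VERSION = "#1.2"
DEFAULT_MIN_TISSUE_SAMPLES = 80


@dataclass
class ExpressionMatrix:
    """A genes × samples table of non-negative expression values (RPKM).

    ``data`` is indexed by gene id with one column per sample id; an optional
    per-gene ``descriptions`` series carries the GCT Description column.
    """

    data: pd.DataFrame
    descriptions: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dupes[:5])}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size and np.nanmin(values) < 0:
            raise ValidationError("expression values must be non-negative")
        if self.descriptions is None:
            self.descriptions = pd.Series("", index=self.data.index, dtype=object)
        elif not self.descriptions.index.equals(self.data.index):
            raise ValidationError("descriptions index must match gene ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[gene_ids], self.descriptions.loc[gene_ids]
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(self.data[sample_ids], self.descriptions)


@dataclass
class SampleLabels:
    """Sample → tissue assignment with an explicit tissue-tag order.

    The tag order is authoritative everywhere downstream (confusion matrices,
    per-tissue accuracy rows); no implicit sorting is ever applied.
    """

    assignments: dict[str, str]
    tissues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tissues:
            seen: dict[str, None] = {}
            for tag in self.assignments.values():
                seen.setdefault(tag, None)
            self.tissues = list(seen)
        if any(not t for t in self.tissues):
            raise ValidationError("tissue tags must be non-empty")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValidationError("tissue tag list contains duplicates")
        known = set(self.tissues)
        stray = {t for t in self.assignments.values() if t not in known}
        if stray:
            raise ValidationError(f"labels use tags missing from tag list: {sorted(stray)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def for_samples(self, sample_ids: list[str]) -> np.ndarray:
        """Tissue tags aligned to ``sample_ids``; unknown sample → error."""
        try:
            return np.array([self.assignments[s] for s in sample_ids], dtype=object)
        except KeyError as exc:
            raise ValidationError(f"sample {exc.args[0]!r} has no tissue label") from None

    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in self.tissues}
        for tag in self.assignments.values():
            out[tag] += 1
        return out

    def subset(self, sample_ids: list[str]) -> "SampleLabels":
        tags = self.for_samples(sample_ids)
        kept = {t for t in tags}
        return SampleLabels(
            dict(zip(sample_ids, tags)), [t for t in self.tissues if t in kept]
        )


def read_gct(path: str | Path) -> ExpressionMatrix:
    """Parse a GCT v1.2 file into an :class:`ExpressionMatrix`.

    Rejects v1.3 (or any other) version lines, dimension mismatches,
    duplicate identifiers and non-numeric cells, reporting the offending
    1-based line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != GCT_VERSION:
        got = lines[0].strip() if lines else "<empty file>"
        raise GCTParseError(
            f"expected GCT version line {GCT_VERSION!r}, got {got!r} "
            "(only the v1.2 dialect is supported)",
            line=1,
        )
    if len(lines) < 3:
        raise GCTParseError("file truncated before the header line", line=len(lines))
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise GCTParseError("dimensions line must be '<n_genes>\\t<n_samples>'", line=2)
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except ValueError:
        raise GCTParseError(f"non-integer dimensions {dims[:2]!r}", line=2) from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise GCTParseError("header must start with 'Name\\tDescription'", line=3)
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise GCTParseError(
            f"declared {n_samples} samples but header lists {len(sample_ids)}", line=3
        )
    body = [ln for ln in lines[3:] if ln != ""]
    if len(body) != n_genes:
        raise GCTParseError(
            f"declared {n_genes} genes but found {len(body)} data rows",
            line=3 + len(lines[3:]),
        )
    gene_ids: list[str] = []
    descriptions: list[str] = []
    values = np.empty((n_genes, n_samples), dtype=float)
    for row, ln in enumerate(body):
        fields = ln.split("\t")
        if len(fields) != n_samples + 2:
            raise GCTParseError(
                f"expected {n_samples + 2} columns, found {len(fields)}", line=4 + row
            )
        gene_ids.append(fields[0])
        descriptions.append(fields[1])
        try:
            values[row] = fields[2:]
        except ValueError:
            bad = next(f for f in fields[2:] if not _is_number(f))
            raise GCTParseError(f"non-numeric cell {bad!r}", line=4 + row) from None
    index = pd.Index(gene_ids, name="Name")
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique()
        raise GCTParseError(f"duplicate gene ids: {list(dupes[:5])}")
    if len(set(sample_ids)) != len(sample_ids):
        raise GCTParseError("duplicate sample ids in header", line=3)
    return ExpressionMatrix(
        pd.DataFrame(values, index=index, columns=sample_ids),
        pd.Series(descriptions, index=index, dtype=object),
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write ``matrix`` in the GCT v1.2 dialect (17 significant digits, so
    ``read_gct(write_gct(m)) == m`` at float64 precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(GCT_VERSION + "\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        values = matrix.data.to_numpy()
        for i, gene in enumerate(matrix.gene_ids):
            row = "\t".join(repr(float(v)) for v in values[i])
            fh.write(f"{gene}\t{matrix.descriptions.iloc[i]}\t{row}\n")


def read_labels(path: str | Path) -> SampleLabels:
    """Read a two-column (SAMPID, SMTS) TSV; tissue order is first appearance."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["SAMPID", "SMTS"]:
        raise ValidationError(
            f"label file must have header 'SAMPID\\tSMTS', got {list(df.columns[:2])}"
        )
    if df["SAMPID"].duplicated().any():
        dupes = df.loc[df["SAMPID"].duplicated(), "SAMPID"].unique()
        raise ValidationError(f"duplicate SAMPID entries: {list(dupes[:5])}")
    return SampleLabels(dict(zip(df["SAMPID"], df["SMTS"])))


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"SAMPID": list(labels.assignments), "SMTS": list(labels.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def filter_expressed_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep genes with at least one strictly non-zero value; order preserved."""
    mask = (matrix.data.to_numpy() != 0.0).any(axis=1)
    return ExpressionMatrix(matrix.data.loc[mask], matrix.descriptions.loc[mask])


def filter_tissues_by_min_samples(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    min_n: int = DEFAULT_MIN_TISSUE_SAMPLES,
) -> tuple[ExpressionMatrix, SampleLabels]:
    """Drop every sample of any tissue represented by fewer than ``min_n``
    samples, updating the tissue tag list accordingly."""
    tags = labels.for_samples(matrix.sample_ids)  # validates full labeling
    counts = pd.Series(tags).value_counts()
    keep_tissues = [t for t in labels.tissues if counts.get(t, 0) >= min_n]
    if not keep_tissues:
        raise ValidationError(f"no tissue has at least {min_n} samples")
    keep_set = set(keep_tissues)
    kept_samples = [s for s, t in zip(matrix.sample_ids, tags) if t in keep_set]
    new_labels = SampleLabels(
        {s: labels.assignments[s] for s in kept_samples}, keep_tissues
    )
    return matrix.subset_samples(kept_samples), new_labels
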