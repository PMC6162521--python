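"""Synthetic tissue-labeled expression data with known planted structure.

The generator emulates the statistical shape of a bulk RNA-seq RPKM panel
over many tissues without any real data: a log-normal background of
uninformative genes, plus two planted gene classes that mirror the two
notions of tissue specificity —

* **quantitative** genes: expressed (non-zero) in every tissue but with a
  tissue-dependent shift of the log-mean, drawn once per gene and tissue
  from N(0, effect_sd²); values are floored at a small positive constant so
  they are never exactly zero;
* **enriched** genes: high in one home tissue (multiplied by
  ``enrichment_fold``) and near-absent elsewhere — non-home values are
  shrunk by a small leak factor and half of them are set to exactly 0, so
  the expressed-gene filter has real work to do.

Home tissues for enriched genes are assigned round-robin.  One
``SeedSequence`` is split into per-gene-class child streams in a fixed,
documented order (noise, quantitative, enriched, zero-mask), so adding a
gene class never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import ExpressionMatrix, SampleLabels

__all__ = ["SyntheticSpec", "GeneratedDataset", "generate_dataset", "split_train_test"]

_LEAK_FACTOR = 0.02  # non-home enriched values keep 2% of their magnitude
_ZERO_FRACTION = 0.5  # fraction of non-home enriched values zeroed exactly


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults give 25 tissues of 40 samples — a desk-scale stand-in for a
    multi-tissue RPKM panel with unequal real-world class sizes available by
    passing an explicit ``samples_per_tissue``.
    """

    n_tissues: int = 25
    samples_per_tissue: list[int] = field(default_factory=lambda: [40] * 25)
    n_quant_genes: int = 30
    n_enriched_genes: int = 0
    n_noise_genes: int = 1500
    base_log_mean: float = 1.0
    base_log_sd: float = 1.0
    effect_sd: float = 1.0
    enrichment_fold: float = 50.0
    floor: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_tissues < 2:
            raise ValidationError("n_tissues must be >= 2")
        if len(self.samples_per_tissue) != self.n_tissues:
            raise ValidationError(
                f"samples_per_tissue has {len(self.samples_per_tissue)} entries "
                f"for n_tissues={self.n_tissues}"
            )
        if any(n < 1 for n in self.samples_per_tissue):
            raise ValidationError("every samples_per_tissue entry must be >= 1")
        for name in ("n_quant_genes", "n_enriched_genes", "n_noise_genes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.base_log_sd <= 0:
            raise ValidationError("base_log_sd must be > 0")
        if self.effect_sd < 0:
            raise ValidationError("effect_sd must be >= 0")
        if self.enrichment_fold < 1:
            raise ValidationError("enrichment_fold must be >= 1")
        if self.floor < 0:
            raise ValidationError("floor must be >= 0")
        if self.n_quant_genes > 0 and self.floor == 0:
            raise ValidationError(
                "floor must be > 0 when quantitative genes are planted "
                "(they are expressed in all tissues by definition)"
            )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        stray = set(raw) - known
        if stray:
            raise ValidationError(f"unknown config fields: {sorted(stray)}")
        return cls(**raw)


@dataclass
class GeneratedDataset:
    """A generated matrix with labels and the planted ground truth."""

    matrix: ExpressionMatrix
    labels: SampleLabels
    gene_roles: dict[str, str]  # gene id -> quantitative | enriched | noise
    enriched_home: dict[str, str]  # enriched gene id -> home tissue tag


def generate_dataset(spec: SyntheticSpec) -> GeneratedDataset:
    """Draw one dataset; bit-for-bit reproducible for a given spec."""
    spec.validate()
    tissues = [f"T{j + 1}" for j in range(spec.n_tissues)]
    sample_tissue = np.repeat(tissues, spec.samples_per_tissue)
    n_samples = len(sample_tissue)
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]

    # fixed child-stream order: changing one class leaves the others intact
    ss = np.random.SeedSequence(spec.seed)
    rng_noise, rng_quant, rng_enr, rng_zero = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []
    gene_roles: dict[str, str] = {}
    enriched_home: dict[str, str] = {}

    if spec.n_quant_genes:
        shifts = rng_quant.normal(
            0.0, spec.effect_sd, size=(spec.n_quant_genes, spec.n_tissues)
        )
        tissue_index = {t: j for j, t in enumerate(tissues)}
        col_shift = shifts[:, [tissue_index[t] for t in sample_tissue]]
        log_values = rng_quant.normal(
            spec.base_log_mean + col_shift, spec.base_log_sd
        )
        blocks.append(np.maximum(np.exp(log_values), spec.floor))
        ids = [f"QTS{i + 1:04d}" for i in range(spec.n_quant_genes)]
        gene_ids += ids
        gene_roles.update({g: "quantitative" for g in ids})

    if spec.n_enriched_genes:
        values = np.exp(
            rng_enr.normal(
                spec.base_log_mean, spec.base_log_sd, size=(spec.n_enriched_genes, n_samples)
            )
        )
        homes = [tissues[i % spec.n_tissues] for i in range(spec.n_enriched_genes)]
        home_mask = np.array(
            [sample_tissue == h for h in homes]
        )  # genes × samples
        values = np.where(home_mask, values * spec.enrichment_fold,
                          values * _LEAK_FACTOR)
        zero_mask = (~home_mask) & (
            rng_zero.random(values.shape) < _ZERO_FRACTION
        )
        values[zero_mask] = 0.0
        blocks.append(values)
        ids = [f"ENR{i + 1:04d}" for i in range(spec.n_enriched_genes)]
        gene_ids += ids
        gene_roles.update({g: "enriched" for g in ids})
        enriched_home.update(dict(zip(ids, homes)))

    if spec.n_noise_genes:
        blocks.append(
            np.exp(
                rng_noise.normal(
                    spec.base_log_mean, spec.base_log_sd,
                    size=(spec.n_noise_genes, n_samples),
                )
            )
        )
        ids = [f"NOISE{i + 1:05d}" for i in range(spec.n_noise_genes)]
        gene_ids += ids
        gene_roles.update({g: "noise" for g in ids})

    if not blocks:
        raise ValidationError("spec plants no genes at all")
    matrix = ExpressionMatrix(
        pd.DataFrame(np.vstack(blocks), index=pd.Index(gene_ids, name="Name"),
                     columns=sample_ids)
    )
    labels = SampleLabels(dict(zip(sample_ids, sample_tissue)), tissues)
    return GeneratedDataset(matrix, labels, gene_roles, enriched_home)


def split_train_test(
    dataset: GeneratedDataset, test_fraction: float, seed: int
) -> tuple[GeneratedDataset, GeneratedDataset]:
    """Per-tissue stratified split into disjoint train/test datasets.

    The test side receives ``round(test_fraction · n_t)`` samples of each
    tissue (at least 1, at most n_t − 1); gene set and roles are shared.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie in (0, 1)")
    counts = dataset.labels.counts()
    tiny = [t for t, c in counts.items() if c < 2]
    if tiny:
        raise ValidationError(f"tissues with a single sample cannot be split: {tiny}")
    rng = np.random.default_rng(seed)
    sample_ids = np.array(dataset.matrix.sample_ids, dtype=object)
    tags = dataset.labels.for_samples(list(sample_ids))
    test_ids: list[str] = []
    for t in dataset.labels.tissues:
        members = sample_ids[tags == t]
        n_test = int(np.clip(round(test_fraction * len(members)), 1, len(members) - 1))
        test_ids += list(rng.choice(members, size=n_test, replace=False))
    test_set = set(test_ids)
    train_ids = [s for s in sample_ids if s not in test_set]
    test_ids = [s for s in sample_ids if s in test_set]

    def _subset(ids: list[str]) -> GeneratedDataset:
        return GeneratedDataset(
            dataset.matrix.subset_samples(ids),
            dataset.labels.subset(ids),
            dataset.gene_roles,
            dataset.enriched_home,
        )

    return _subset(train_ids), _subset(test_ids)
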