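"""Simulate a tissue-labeled expression panel and apply the dataset filters.

Generates a small 6-tissue RPKM-like matrix with planted quantitatively
tissue-specific genes, tissue-enriched genes and pure noise, then applies
the two preprocessing rules: drop genes never expressed (all-zero), and drop
tissues with too few samples.
"""

from tissueclf import (
    SyntheticSpec,
    filter_expressed_genes,
    filter_tissues_by_min_samples,
    generate_dataset,
)

spec = SyntheticSpec(
    n_tissues=6,
    samples_per_tissue=[30, 30, 30, 30, 30, 12],
    n_quant_genes=10,
    n_enriched_genes=6,
    n_noise_genes=200,
    effect_sd=1.0,
    seed=7,
)
dataset = generate_dataset(spec)
matrix, labels = dataset.matrix, dataset.labels
print(f"simulated: {matrix.n_genes} genes x {matrix.n_samples} samples, "
      f"{len(labels.tissues)} tissues")

# tissues below the size cutoff are excluded before anything else
matrix, labels = filter_tissues_by_min_samples(matrix, labels, min_n=20)
print(f"after tissue-size filter (>=20): {matrix.n_samples} samples, "
      f"tissues {labels.tissues}")

# a gene counts as expressed if any sample has a strictly non-zero value;
# enriched genes are exactly zero outside their home tissue half the time,
# so a few can vanish entirely once their home tissue is dropped
matrix = filter_expressed_genes(matrix)
print(f"after expressed-gene filter: {matrix.n_genes} genes")

roles = dataset.gene_roles
kept_roles = {r: sum(1 for g in matrix.gene_ids if roles[g] == r)
              for r in ("quantitative", "enriched", "noise")}
print(f"planted genes surviving the filters: {kept_roles}")
# quantitative genes are never zero by construction, so all 10 survive
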