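"""Rank genes by minimum-redundancy maximum-relevance mutual information.

Expression is discretized into three states per gene (below / within / above
mean +- 1 SD); the greedy ranking then alternates maximal relevance to the
tissue label against minimal redundancy with genes already chosen.  On
planted data the known informative genes should fill the top of the list.
"""

from tissueclf import (
    SyntheticSpec,
    discretize_expression,
    generate_dataset,
    rank_features_mrmr,
)

spec = SyntheticSpec(
    n_tissues=8,
    samples_per_tissue=[25] * 8,
    n_quant_genes=12,
    n_enriched_genes=0,
    n_noise_genes=400,
    effect_sd=1.2,
    seed=21,
)
dataset = generate_dataset(spec)
disc = discretize_expression(dataset.matrix, alpha=1.0)
ranked = rank_features_mrmr(disc, dataset.labels, criterion="MID", top_n=20)

print("rank  gene       score(bits)  planted role")
for pos, (gene, score) in enumerate(zip(ranked.gene_ids, ranked.scores), start=1):
    print(f"{pos:>4}  {gene:<9} {score:>10.4f}  {dataset.gene_roles[gene]}")

planted = {g for g, r in dataset.gene_roles.items() if r == "quantitative"}
hits = len(planted & set(ranked.gene_ids[:12]))
print(f"\n{hits}/12 planted quantitative genes occupy the first 12 ranks;")
print("the score is MI with the tissue label minus mean MI with genes above.")
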