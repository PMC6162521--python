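# tissueclf

Classify human tissues from **quantitative** gene-expression signatures.

Most tissue-specificity catalogs focus on genes that are switched on in one
tissue and off elsewhere.  This package implements the complementary
analysis: finding genes that are expressed almost everywhere but at
systematically different *levels* between tissues, and showing that a small
panel of them suffices to tell tissues apart.  It is aimed at
computational biologists working with multi-tissue bulk RNA-seq panels
(GCT expression matrices with sample→tissue labels) who want a
reproducible, testable version of the following pipeline:

1. **Filtering** — keep genes expressed (non-zero) in at least one sample;
   drop tissues with fewer than 80 samples.
2. **mRMR ranking** — discretize each gene at mean ± σ into three states,
   then greedily rank genes by mutual information with the tissue label
   penalized by redundancy with genes already chosen:
   score(f) = I(f; c) − |S|⁻¹ Σ_{s∈S} I(f; s).
3. **Incremental feature selection (IFS)** — for each prefix
   F_i = [f₁ … f_i] of the ranked list, 10-fold cross-validate a
   polynomial-kernel SVM (SMO-style defaults: degree 1, C = 1,
   tolerance 10⁻³, one-vs-one) and keep the prefix with the best score.
4. **Scoring** — per-tissue accuracy ACC_j = n_j/N_j, overall accuracy
   TACC = Σn_j/ΣN_j, and the multiclass Matthews correlation coefficient
   MCC = cov(X,Y)/√(cov(X,X)·cov(Y,Y)) over the truth/prediction indicator
   matrices — a balanced score in [−1, 1] that is robust to the highly
   unequal tissue sizes.
5. **Baselines** — the same cross-validation harness applied to any
   externally supplied gene panel, and a one-vs-rest Welch t-test selection
   (union of each tissue's top-19 over-expressed genes).

Because the method's claims are about recovering planted structure, the
package ships a first-class synthetic-data generator that emulates a
25-tissue RPKM panel with known quantitatively tissue-specific genes,
single-tissue-enriched genes and background noise, so every stage can be
validated without any external download.

## Worked example

`examples/03_ifs_svm_scan.py` simulates 8 tissues × 25 samples with 12
planted quantitatively tissue-specific genes among 400 noise genes, ranks
genes by mRMR and scans prefixes of the list:

```
genes  MCC     TACC
    2  0.323  0.400
    4  0.637  0.680
    6  0.773  0.800
    8  0.853  0.870
   10  0.875  0.890
   12  0.926  0.935
   ...
optimal model: 18 genes, 10-fold CV MCC 0.932, overall accuracy 0.940
per-tissue accuracy: T1=1.00 T2=0.96 T3=0.96 T4=0.92 T5=1.00 T6=0.84 T7=0.88 T8=0.96
```

The curve climbs steeply while informative genes enter the prefix and
flattens once only noise is appended; the selected 18-gene model classifies
94% of held-out samples correctly with a multiclass MCC of 0.93.  The other
examples show simulation + filtering (`01`), the ranked list with planted
roles (`02`), and the baseline comparisons (`04`).

The same pipeline is scriptable from the shell:

```sh
tissueclf simulate --config config.yaml --out-dir data/
tissueclf run-all --gct data/expression.gct --labels data/labels.tsv \
    --out-dir results/ --i-max 80 --step 2
```

`run-all` writes the ranked list, the IFS curve (TSV + plot), the optimal
gene panel, per-tissue train-CV and held-out test reports, and a log with
both seeds and library versions.

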