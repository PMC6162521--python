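# Methods

## Problem setting

Given a genes × samples matrix of non-negative expression values (RPKM
scale) and a tissue label per sample, the pipeline selects a compact gene
panel whose expression *levels* discriminate the tissues, and quantifies
how well an SVM over that panel classifies samples.  The emphasis is on
quantitatively tissue-specific genes — expressed in all or most tissues but
at tissue-dependent levels — as opposed to classical tissue-enriched
markers that are on in one tissue and off elsewhere.

## Data model and filtering

Expression matrices are read and written in the GCT v1.2 dialect (version
line `#1.2`, dimensions line, `Name`/`Description` columns).  v1.3 files
are rejected outright rather than partially parsed; a bit-exact dialect is
easier to reason about than silent permissiveness.  Labels are a two-column
`SAMPID`/`SMTS` TSV, with the tissue-tag order taken from first appearance
and threaded explicitly through every downstream computation — no function
ever sorts tags implicitly.

Two filters mirror standard multi-tissue panel preprocessing:

* genes are retained if **any** sample has a strictly non-zero value.  The
  criterion is literal `!= 0.0` with no epsilon: zero RPKM means no reads.
* tissues with fewer than `min_n` samples (default 80) are dropped, before
  the gene filter when both are requested.  Both filters are idempotent and
  commute on the final matrix.

## Discretization and mutual information

Mutual information is estimated after discretizing each gene into three
states at mean ± α·σ (α = 1 by default, population σ): −1 below, +1 above,
0 between; a constant gene maps entirely to 0.  This is the standard
treatment of continuous inputs in mRMR practice; α is exposed in the API
and CLI.  MI between discrete sequences is the plug-in estimate over the
empirical joint table, in bits.  The log base cancels in rankings but is
pinned so reported scores are reproducible.  Zero-probability cells
contribute exactly 0.

## mRMR ranking

The ranking is the greedy difference-form (MID) criterion: the first gene
maximizes relevance I(f; c), where the tissue label c is a single
25-symbol categorical variable (not one-vs-rest); each later gene maximizes
I(f; c) − mean_{s∈S} I(f; s) over the not-yet-selected genes.  The
quotient form (MIQ) is available; its denominator is guarded by
max(mean redundancy, 10⁻¹²) so early steps with zero redundancy stay
defined.  Ties break to input gene order, making reruns bit-identical.
Each pairwise MI is computed exactly once: when a gene is selected, its MI
against all remaining candidates is evaluated in a single vectorized pass
and accumulated into per-candidate redundancy sums.

## Classifier

The SVM mirrors the defaults of the classic SMO tool: polynomial kernel of
degree 1 (inner product, γ = 1, coef0 = 0), C = 1, tolerance 0.001,
one-vs-one multiclass voting, per-feature min–max normalization to [0, 1]
fitted on training data only.  The quadratic-programming solver is
scikit-learn's `SVC`; the package's contract is the surrounding harness.

Expression enters the model as **log2(x + 1)** by default.  This was a
genuinely open design point: with raw RPKM-scale values, min–max scaling is
set by the extreme upper tail, compressing almost all samples into a tiny
corner of feature space and crippling a degree-1 kernel (on planted
synthetic data, cross-validated MCC ≈ 0.5 raw versus ≈ 0.97 after log2 at
the same feature count).  Tissue-level effects in positive, right-skewed
expression data are multiplicative, so the log scale is where a linear
decision boundary is natural.  `log2_transform=False` (CLI `--no-log2`)
restores raw modeling for sensitivity analysis.

## Cross-validation

Stratified 10-fold cross-validation, shuffled with a fixed, logged seed.
The fold partition is generated once per pipeline run and reused for every
feature set, so differences along the IFS curve reflect features rather
than fold resampling noise.  Normalization (and the log transform) are
refitted inside each training fold; an injected extreme outlier in a test
fold provably cannot move the transforms of the fold trained without it
(pinned by test).  Out-of-fold predictions are pooled into one confusion
matrix per feature set.  Stratification is not strictly required by the
method but stabilizes folds when the smallest tissue has ~83 samples.

## Measurements

With truth and prediction encoded as n × N 0/1 indicator matrices Y and X
(one row per sample, rows sum to 1):

* ACC_j = n_j / N_j — correct over total per tissue;
* TACC = Σ n_j / Σ N_j — equal to the N_j-weighted mean of ACC_j (identity
  pinned by test);
* multiclass MCC = cov(X,Y)/√(cov(X,X)·cov(Y,Y)), where cov averages the
  column-wise centered covariances with a 1/N factor.  The factor cancels
  in the ratio but is kept so intermediate values match their definition.
  For N = 2 this reduces exactly to the classical binary Matthews
  coefficient (verified to 10⁻¹² against the closed formula).

When the denominator is exactly zero — constant predictions or a single
represented class — the MCC is defined here as 0: such a classifier is no
better than random.  This convention is a package choice (no authoritative
definition exists for the degenerate case) and is pinned by tests.

## Incremental feature selection

Prefixes F_i of the ranked list are scanned for i in [i_min, i_max]
(defaults 4–500) with an optional step > 1 for coarse scans.  The optimum
is the maximal-MCC point, ties to the smallest i — parsimony is the
defensible default when the curve plateaus.  The curve stores the full
per-point result, so per-tissue reports need no recomputation.

## Baselines

* **Gene-list evaluation** restricts the feature space to a user-supplied
  panel (e.g. a curated tissue-enriched list) and runs the identical CV
  harness; absent genes are warned about and dropped.  With the same fold
  seed, results are directly comparable to the IFS optimum.
* **t-test selection** ranks genes per tissue by a Welch two-sample t of
  that tissue versus all others, descending, then unions each tissue's
  top-k (default 19).  Welch's unequal-variance form is used because
  one-vs-rest group sizes are badly unbalanced.  Under-expressed genes
  (t < 0) are excluded; exact ties (t = 0, e.g. constant genes) rank in
  input order via a stable sort, so in the degenerate case where every
  tissue produces the same ranking the union is exactly k.  P-values
  (two- and one-sided) are reported but not used for selection, so no
  multiple-testing correction applies.

## Synthetic data generator

The generator emulates the statistical shape of a multi-tissue RPKM panel:

| parameter | default | meaning |
|---|---|---|
| `n_tissues`, `samples_per_tissue` | 25 × 40 | class structure; unequal sizes supported |
| `base_log_mean`, `base_log_sd` | 1.0, 1.0 | log-normal background (positive, right-skewed) |
| `effect_sd` | 1.0 | SD of per-gene, per-tissue log-mean shifts of quantitative genes |
| `enrichment_fold` | 50 | home-tissue multiplier for enriched genes |
| `floor` | 0.01 | minimum value of quantitative genes (never zero) |

Noise genes are i.i.d. log-normal regardless of tissue.  Quantitative
genes draw one log-mean shift per (gene, tissue) from N(0, effect_sd²) —
expressed everywhere, informative through level differences.  Enriched
genes get a round-robin home tissue, a fold elevation at home, a 2% leak
factor elsewhere, and exactly-zero values injected into half the non-home
samples so the expressed-gene filter has genuine work.  One `SeedSequence`
spawns child streams in fixed order (noise, quantitative, enriched,
zero-mask), so changing one gene class never perturbs another's draws.

Default effect sizes are free parameters of the generator, chosen once as
plausible for log-scale tissue effects; they are not estimates of any real
panel.  The generator does not model library-size normalization, batch
effects, gene–gene correlation beyond the planted classes, or count-level
(negative binomial) noise — so passing recovery tests demonstrate the
pipeline's correctness and sensitivity under a clean generative model, not
its performance on real GTEx-like data.

## Problem sizes used in validation

The synthetic-recovery experiment runs at 25 tissues × 40 samples with 30
planted quantitative genes and 1500 noise genes, scanning prefixes 4–80 in
steps of 2 — large enough for 25-class structure with realistic imbalance
in difficulty, small enough for routine re-runs.  Unit tests use 4–8
tissue datasets of a few hundred samples.

## Known limitations

* The MI estimator is the raw plug-in; no bias correction. Fine for
  ranking (all genes share the same sample size), not for absolute MI.
* mRMR with thousands of retained candidates is O(top_n × n_genes)
  vectorized MI passes; ranking far beyond the IFS scan ceiling is wasted
  work, so `top_n` should normally match the scan maximum.
* Exact gene-for-gene agreement with other mRMR implementations is not
  expected: discretization, MI base and tie-breaking all vary across
  tools.
* The IFS optimum is selected on the same cross-validation used to report
  performance; there is no nested CV, so the reported optimum MCC is
  mildly optimistic.  The held-out test split in `run-all` gives the
  unbiased number.
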