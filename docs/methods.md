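# Methods

## Model and procedure

`gsoa` scores a gene set by the out-of-sample discriminative power of its
omic measurements. Given a feature-by-sample matrix (features annotated to
genes, possibly several features per gene) and a two-class sample labeling,
each gene set is evaluated in three steps: (1) restrict the matrix to
features whose gene belongs to the set; (2) predict every sample's class by
stratified k-fold cross-validation of an RBF-kernel soft-margin SVM; (3)
summarize the pooled out-of-fold decision values as the AUC. The SVM is
deliberately nonlinear: pathway genes act in concert, so the class signal may
live in a multivariate, multidirectional pattern (some members up, some
down, with inter-gene dependence) that per-gene or unidirectional
set-statistics miss.

Assumptions worth stating: measurements are already preprocessed to a
gene-level matrix on a roughly continuous scale (the method does no
platform-specific normalization beyond per-feature standardization); gene
names match the gene-set collection by exact, case-sensitive string
comparison; exactly two classes, each with at least k samples after sample
intersection.

### Significance

Raw AUC grows with gene-set size even on uninformative data — more features
give the classifier more room to overfit fold structure — so AUCs are never
compared across sets directly. Instead each observed AUC is referred to a
null distribution of AUCs from random gene sets drawn uniformly (without
replacement) from the genes present in the loaded data, evaluated with the
identical cross-validation configuration. Null sizes are binned
(1, 5, 10, 25, 50, 75, 100, 125, 150, 200, 250, 300, 400, 500; larger sets
use the top bin) with each actual set rounded up to its bin, 100 random sets
per bin by default. The empirical P value is

    p = (#{null AUC strictly greater than observed} + 1) / (n_null + 1)

The +1 pseudocount keeps p strictly positive (a valid permutation P value);
its floor, 1/(n_null+1), is user-adjustable via `--null-repeats` when more
resolution is needed. Ties between null and observed AUC do not count
against the set. All sets in a bin are compared against the *same* null
sample, so P values are coherent within a bin. Benjamini–Hochberg step-up
adjustment (implemented directly; verified element-wise against the
statsmodels reference in the test suite) converts P values to FDRs.

Sets are binned by the number of *distinct set genes found in the data*,
because that is the quantity the null draw matches: a random draw of s genes
takes every feature row of those genes in every omic type, exactly as a real
set does. With one feature per gene and one omic type this equals the
feature count.

### Multi-omic integration

Two routes are provided. *Merged* mode concatenates, per gene set, the
matching features of every omic type into one feature space — each
technology contributes whichever set genes it measures — and restricts
samples to those measured on all types; one SVM then integrates the types.
*Rank-combined* mode analyzes each omic type separately and combines the
per-omic P values: within each table gene sets are ranked by P (average rank
on ties), a set's statistic is its mean rank across tables, and its combined
P is the Monte-Carlo lower-tail probability of that mean rank under
independent uniform rankings (10,000 seeded permutations by default;
strict-inequality counting with the same +1 pseudocount). The Monte-Carlo
mean-rank construction is this package's concrete instantiation of
rank-based combination; sets skipped on any platform are excluded from the
combined table rather than imputed.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k_folds` | 5 | CV folds; must not exceed the smaller class (hard error, never silently reduced) |
| `cost` (C) | 1.0 | SVM soft-margin penalty |
| `gamma` | 1/n_features | RBF width; on standardized features this matches the common "scale" heuristic |
| `tune` | off | nested-CV grid search per outer fold; grid C ∈ {0.01,0.1,1,10,100}, γ ∈ {1e-4,…,1}·(1/n_features); ties → smaller C, then smaller γ |
| `balanced_weights` | on | class-frequency-inverse SVM weights, counteracting class imbalance |
| `null_repeats` | 100 | null AUCs per size bin; P floor = 1/(repeats+1) |
| `min_set_overlap` | 2 | minimum data features to score a set — a single-feature "multivariate pattern" is a contradiction |
| `positive_class` | lexicographically second label | AUC orientation only; the null shares the convention, so significance is orientation-invariant |
| `seed` | 0 | drives fold shuffling, null draws, rank permutations; fixed seed ⇒ byte-identical outputs |

Numerical conventions: standardization uses training-fold statistics only
(no leakage from held-out samples) with the population SD (divide by n);
zero-variance features map to all-zeros in both partitions. AUC counts tied
decision values as one half. Missing cells (token `NA`, configurable) cause
the whole feature row to be dropped at load time, with a logged count —
imputation is out of scope.

## The simulated-data generator

`SimulationDesign`/`generate_dataset` emulate a two-class bulk-expression
study: independent Gaussian background genes (SD `noise_sd`), plus signal
blocks in which a chosen number of genes per set (i) shift between classes
by `effect_size` SD with gene-to-gene alternating sign (multidirectional by
design; a `unidirectional` toggle exists) and (ii) share an equicorrelation
`dependence` via a one-factor construction. Gene sets are non-overlapping so
the truth table is unambiguous. Defaults model a 100-sample, 20,000-gene
study with 20 signal sets of 50 genes (10 signal genes each, 1 SD shift,
correlation 0.3) and 40 null sets of 50 genes — a subtle-signal regime in
which set-level recovery is expected but not trivial. `evaluate_thresholds`
scores calls against the truth (sensitivity, specificity, Matthews
correlation; MCC defined 0 when its denominator vanishes).

What the generator does *not* emulate: heavy-tailed or count-valued
measurements, batch effects, overlapping pathways, correlation between
signal and background genes, and technology-specific missingness. Passing
tests on these simulations therefore demonstrate the machinery's
correctness and calibration, not performance guarantees on any particular
real platform.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` run the full pipeline at
deliberately moderate scale — e.g. 5,000 background genes instead of 20,000
for the sensitivity study, and 60-sample noise designs for calibration
properties — sizes chosen so the whole suite completes in well under a
minute while keeping every statistical conclusion comfortably inside its
assertion band (the sensitivity margin at these settings is roughly
ten-fold). Scaling `n_genes` up changes runtime, not the logic: per-set cost
depends on the set's feature count, not the matrix width.

## Known limitations and open choices

* Whether AUC should be computed per fold and averaged, or on pooled
  out-of-fold scores, is a genuinely open design point; pooling was chosen
  for stability with small folds and because one AUC per set matches the
  output schema.
* Train-fold-only standardization is the leakage-safe choice; a whole-matrix
  scaler would be marginally more stable for tiny folds but lets held-out
  samples influence the transform.
* Only the RBF SVM ships, although any classifier producing continuous
  decision values would fit the seam (`cross_validated_scores` is the only
  consumer).
* The empirical null is recomputed per run (per seed); persisting and
  reusing null tables across collections with identical data and
  configuration would be a straightforward optimization.
* P values are lower-bounded by 1/(null_repeats+1); studies needing deep
  FDR resolution should raise `--null-repeats` (e.g. 999 for a 0.001 floor)
  at proportional cost.
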