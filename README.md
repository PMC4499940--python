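# gsoa — supervised gene-set prioritization from omic data

`gsoa` asks, for every gene set in a collection: *how accurately can a
classifier separate two groups of samples using only the omic measurements of
that set's genes?* Gene sets whose members jointly discriminate the classes —
even when individual genes move in opposite directions, and even when no
single gene is strongly differential — rise to the top. The intended users
are researchers with a preprocessed gene-level matrix (RNA-seq, microarray,
copy number, mutation calls, ...) who want pathway-level hypotheses about
what distinguishes two phenotypes.

## Method

For each gene set *S* over a samples-by-genes matrix **X** with binary class
labels **y**:

1. **Subset** — keep the feature rows whose gene is in *S* (all omic types
   contribute whichever of their features map to *S*).
2. **Classify** — stratified *k*-fold cross-validation (default *k* = 5) of a
   soft-margin SVM with an RBF kernel (default *C* = 1, γ = 1/|features|).
   Features are mean-centered and scaled to unit variance with statistics
   from the training folds only. Every sample gets one out-of-fold decision
   value.
3. **Score** — AUC of the pooled out-of-fold decision values: the
   Mann–Whitney probability that a random positive sample outranks a random
   negative one. AUC ≈ 0.5 is chance; 1.0 is perfect separation.

Because larger gene sets get higher AUCs even on noise, significance is
empirical and **size-matched**: random gene sets are drawn from the genes
present in the data at binned sizes (1, 5, 10, 25, 50, 75, 100, 125, 150,
200, 250, 300, 400, 500+; each actual set's size rounds up to its bin),
cross-validated identically (100 repeats per bin by default), and

&nbsp;&nbsp;&nbsp;&nbsp;*P* = (#{null AUC > observed AUC} + 1) / (#null + 1),

followed by Benjamini–Hochberg FDR across sets. Multiple omic types can be
**merged** into one feature space (samples restricted to those measured on
all types) or analyzed separately and combined by a seeded Monte-Carlo
mean-rank *P* value.

## Worked example

Generate a small simulated study (60 samples, 1,000 genes, two signal sets
whose members shift by 1.5 SD with alternating sign and correlation 0.3,
three pure-noise sets) and analyze it:

```python
from gsoa import SimulationDesign, generate_dataset
from gsoa.io import write_omic_matrix, write_class_file, write_gmt

design = SimulationDesign(n_samples=60, n_genes=1000,
                          signal_sets=((40, 15), (30, 10)), n_null_sets=3,
                          null_set_size=30, effect_size=1.5, dependence=0.3,
                          seed=4)
matrix, labels, sets, truth = generate_dataset(design)
write_omic_matrix(matrix, "demo/expression.txt")
write_class_file(labels, "demo/classes.txt")
write_gmt(sets, "demo/sets.gmt")
```

```sh
gsoa run --data demo/expression.txt --classes demo/classes.txt \
         --gene-sets demo/sets.gmt --null-repeats 100 --seed 4 --out demo/out
cat demo/out/results_expression.txt
```

```
gene_set        n_genes n_features      AUC     p_value         FDR
SIGNAL_SET_001  40      40      1       0.009900990099  0.02475247525
SIGNAL_SET_002  30      30      1       0.009900990099  0.02475247525
NULL_SET_002    30      30      0.6288888889    0.5940594059    0.8811881188
NULL_SET_003    30      30      0.4844444444    0.8613861386    0.8811881188
NULL_SET_001    30      30      0.45    0.8811881188    0.8811881188
```

Both planted signal sets are perfectly classified (AUC 1) and beat all 100
size-matched random sets, so their *P* hits the pseudocount floor
1/101 ≈ 0.0099 and survives FDR correction; the noise-only sets land near
chance AUC and stay insignificant. `n_genes` is the annotated set size,
`n_features` the feature rows actually found in the data. A `manifest.json`
records the seed, parameters and input digests needed to reproduce the run
byte for byte.

`gsoa simulate --design design.yaml --out simdir` runs the same pipeline on
a freshly generated dataset and reports sensitivity, specificity and the
Matthews Correlation Coefficient against the known truth at a series of FDR
thresholds. The library API (`gsoa.analyze`, `gsoa.generate_dataset`, ...)
exposes every step for programmatic use.

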