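"""End-to-end runs: load inputs, score every gene set, write ranked tables.

Three analysis modes:

* ``per-omic`` — each input matrix is analyzed on its own; one result table
  per omic type.
* ``merged`` — features from all matrices are concatenated into one feature
  space (restricted to samples measured on every omic type) and a single SVM
  scores each gene set; one table.
* ``rank-combined`` — per-omic analyses followed by a rank-based combination
  of the per-omic P values; per-omic tables plus a combined table.

Every run writes a JSON manifest (seed, parameters, input digests, skipped
sets) sufficient to reproduce it bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io as gio
from .core import ClassifierConfig, cross_validated_scores, compute_auc, \
    intersect_samples, subset_to_gene_set
from .errors import ConfigError, GsoaError, NoFeatureOverlap
from .io import ClassLabels, GeneSetCollection, GeneSetResult, OmicMatrix
from .stats import DEFAULT_COMBINE_PERMUTATIONS, DEFAULT_NULL_REPEATS, \
    bh_fdr, build_null_table, combine_rank_pvalues, size_bin
from .synthetic import DEFAULT_THRESHOLDS, SimulationDesign, \
    evaluate_thresholds, generate_dataset

logger = logging.getLogger(__name__)

MODES = ("per-omic", "merged", "rank-combined")


@dataclass
class RunConfig:
    """All settings of one analysis run (mirrors the CLI flags)."""

    data_paths: Sequence[str]
    class_path: str
    gmt_path: str
    out_dir: str
    mode: str = "per-omic"
    k_folds: int = 5
    cost: float = 1.0
    gamma: float | None = None  # None -> 1/n_features
    tune: bool = False
    null_repeats: int = DEFAULT_NULL_REPEATS
    combine_permutations: int = DEFAULT_COMBINE_PERMUTATIONS
    seed: int = 0
    min_set_overlap: int = 2
    positive_class: str | None = None
    missing_token: str = gio.DEFAULT_MISSING_TOKEN

    def classifier_config(self) -> ClassifierConfig:
        from .core import GAMMA_BY_FEATURES
        return ClassifierConfig(
            k_folds=self.k_folds, cost=self.cost,
            gamma=self.gamma if self.gamma is not None else GAMMA_BY_FEATURES,
            tune=self.tune, seed=self.seed)


@dataclass
class AnalysisOutput:
    """Scored and skipped gene sets from one analysis."""

    results: list[GeneSetResult]
    skipped: dict[str, str] = field(default_factory=dict)


def analyze(matrices: Sequence[OmicMatrix], labels: ClassLabels,
            collection: GeneSetCollection, cfg: ClassifierConfig,
            null_repeats: int = DEFAULT_NULL_REPEATS,
            min_set_overlap: int = 1,
            null_seed: int | None = None) -> AnalysisOutput:
    """Score every gene set in ``collection`` against the loaded data.

    Sequence: intersect samples across matrices and the class file; for each
    set, subset to its features and compute the cross-validated SVM AUC; build
    one null AUC distribution per needed size bin (random gene sets drawn from
    the data's gene universe, ``null_repeats`` each); convert AUCs to
    empirical P values and BH FDRs. Sets overlapping fewer than
    ``min_set_overlap`` feature rows are skipped and reported, not scored.
    """
    matrices, labels = intersect_samples(matrices, labels, cfg.k_folds)

    evaluated = []  # (gene_set, submatrix)
    skipped: dict[str, str] = {}
    for gene_set in collection:
        try:
            sub = subset_to_gene_set(matrices, gene_set.genes)
        except NoFeatureOverlap:
            skipped[gene_set.name] = "no features"
            continue
        if sub.n_features < min_set_overlap:
            skipped[gene_set.name] = (
                f"only {sub.n_features} feature(s), below the "
                f"{min_set_overlap}-feature floor")
            continue
        evaluated.append((gene_set, sub))
    for name, reason in skipped.items():
        logger.info("skipping gene set %s: %s", name, reason)
    if not evaluated:
        return AnalysisOutput([], skipped)

    aucs = []
    bins = []
    for gene_set, sub in evaluated:
        scores = cross_validated_scores(sub, labels, cfg)
        aucs.append(compute_auc(scores, labels))
        # bin by distinct genes found in the data: the null draws gene names
        # from the data universe, so this is the size-matched quantity
        bins.append(size_bin(sub.n_genes))

    null_table = build_null_table(matrices, labels, set(bins), cfg,
                                  repeats=null_repeats, seed=null_seed)
    from .stats import empirical_pvalue
    pvals = [empirical_pvalue(auc, null_table.null_for(b))
             for auc, b in zip(aucs, bins)]
    fdrs = bh_fdr(pvals)

    results = [
        GeneSetResult(set_name=gene_set.name,
                      n_genes_annotated=gene_set.size,
                      n_features_used=sub.n_features,
                      auc=auc, p_value=p, fdr=float(q))
        for (gene_set, sub), auc, p, q in zip(evaluated, aucs, pvals, fdrs)
    ]
    return AnalysisOutput(gio.sort_results(results), skipped)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_combined(results, path: str) -> None:
    import pandas as pd
    omics = sorted(results[0].per_omic_p) if results else []
    rows = [[r.set_name, *(r.per_omic_p[o] for o in omics), r.mean_rank,
             r.combined_p, r.combined_fdr] for r in results]
    cols = ["gene_set", *(f"p_{o}" for o in omics),
            "mean_rank", "combined_p", "combined_FDR"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.10g")


def run_gsoa(config: RunConfig) -> list[str]:
    """Execute a full analysis run; returns the paths written.

    On any error, files written so far are removed so a nonzero exit never
    leaves partial output behind.
    """
    if config.mode not in MODES:
        raise ConfigError(f"unknown mode {config.mode!r}; choose from {MODES}")
    matrices: list[OmicMatrix] = []
    for pattern in config.data_paths:
        matrices.extend(gio.read_omic_matrix(pattern, config.missing_token))
    if config.mode in ("merged", "rank-combined") and len(matrices) < 2:
        raise ConfigError(f"mode {config.mode!r} requires at least 2 omic "
                          "matrices")
    names = [m.omic_name for m in matrices]
    if len(set(names)) != len(names):
        raise ConfigError(f"omic names (file stems) must be unique: {names}")
    labels = gio.read_class_file(config.class_path, config.positive_class)
    collection = gio.read_gmt(config.gmt_path)
    cfg = config.classifier_config()

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    skipped_by_table: dict[str, dict[str, str]] = {}
    try:
        if config.mode == "merged":
            out = analyze(matrices, labels, collection, cfg,
                          config.null_repeats, config.min_set_overlap)
            path = out_dir / "results_merged.txt"
            gio.write_results(out.results, str(path))
            written.append(str(path))
            skipped_by_table["merged"] = out.skipped
        else:
            per_omic: dict[str, list[GeneSetResult]] = {}
            for m in matrices:
                out = analyze([m], labels, collection, cfg,
                              config.null_repeats, config.min_set_overlap)
                path = out_dir / f"results_{m.omic_name}.txt"
                gio.write_results(out.results, str(path))
                written.append(str(path))
                per_omic[m.omic_name] = out.results
                skipped_by_table[m.omic_name] = out.skipped
            if config.mode == "rank-combined":
                combined = combine_rank_pvalues(
                    per_omic, permutations=config.combine_permutations,
                    seed=config.seed)
                path = out_dir / "results_combined.txt"
                _write_combined(combined, str(path))
                written.append(str(path))

        manifest = {
            "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                       for k, v in dataclasses.asdict(config).items()},
            "inputs": {p: _sha256(p)
                       for pattern in config.data_paths
                       for p in gio._expand_pattern(pattern)}
            | {config.class_path: _sha256(config.class_path),
               config.gmt_path: _sha256(config.gmt_path)},
            "skipped_gene_sets": skipped_by_table,
            "outputs": [str(Path(p).name) for p in written],
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
        written.append(str(manifest_path))
    except GsoaError:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise
    return written


def run_simulation(design: SimulationDesign, out_dir: str,
                   thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                   k_folds: int = 5,
                   null_repeats: int = DEFAULT_NULL_REPEATS,
                   min_set_overlap: int = 2) -> list[str]:
    """Generate a simulated dataset, write it in the input file formats, run
    the full analysis on the written files, and score the calls against the
    truth at each threshold. Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, labels, collection, truth = generate_dataset(design)
    data_path = out / "simulated_data.txt"
    class_path = out / "simulated_classes.txt"
    gmt_path = out / "simulated_sets.gmt"
    gio.write_omic_matrix(matrix, str(data_path))
    gio.write_class_file(labels, str(class_path))
    gio.write_gmt(collection, str(gmt_path))

    config = RunConfig(
        data_paths=[str(data_path)], class_path=str(class_path),
        gmt_path=str(gmt_path), out_dir=str(out), mode="per-omic",
        k_folds=k_folds, null_repeats=null_repeats, seed=design.seed,
        min_set_overlap=min_set_overlap)
    written = run_gsoa(config)

    results = gio.read_results(str(out / "results_simulated_data.txt"))
    metrics = evaluate_thresholds(results, truth, thresholds)
    import pandas as pd
    frame = pd.DataFrame(
        [(m.threshold, m.tp, m.fp, m.tn, m.fn,
          m.sensitivity, m.specificity, m.mcc) for m in metrics],
        columns=["threshold", "TP", "FP", "TN", "FN",
                 "sensitivity", "specificity", "MCC"])
    metrics_path = out / "threshold_metrics.txt"
    frame.to_csv(metrics_path, sep="\t", index=False, float_format="%.6g")
    return [str(data_path), str(class_path), str(gmt_path),
            *written, str(metrics_path)]
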