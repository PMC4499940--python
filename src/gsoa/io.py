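"""Readers and writers for the three input formats and the result table.

Input formats
-------------
*Omic matrix*: tab-delimited; a header row of sample identifiers; every data
row starts with a gene name followed by one numeric value per sample. Multiple
rows may share a gene name (e.g. several probes or transcripts per gene). A
header that carries a leading label for the gene column is also accepted.
Several matrices (one per omic type) can be selected with a wildcard pattern.

*Class file*: headerless, two tab-separated columns: sample identifier and
class label. Exactly two classes, each with at least two samples.

*Gene sets*: GMT (Gene Matrix Transposed) as distributed by the Molecular
Signatures Database — set name, descriptor, then the member genes.
"""

from __future__ import annotations

import glob
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: cell content treated as a missing measurement by default
DEFAULT_MISSING_TOKEN = "NA"

RESULT_COLUMNS = ("gene_set", "n_genes", "n_features", "AUC", "p_value", "FDR")


@dataclass
class OmicMatrix:
    """One omic type's feature-by-sample measurements.

    ``values`` has one row per genomic feature and one column per sample;
    ``feature_genes[i]`` is the gene annotated to row ``i`` (names need not be
    unique — several features may measure the same gene).
    """

    omic_name: str
    sample_ids: list[str]
    feature_genes: np.ndarray  # shape (n_features,), dtype object
    values: np.ndarray  # shape (n_features, n_samples), float64

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def genes(self) -> set[str]:
        """Distinct gene names present in this matrix."""
        return set(self.feature_genes.tolist())

    def restrict_samples(self, sample_ids: Sequence[str]) -> "OmicMatrix":
        """Return a copy restricted to ``sample_ids`` in the given order."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as exc:  # pragma: no cover - guarded by callers
            raise InputError(f"sample {exc.args[0]!r} absent from matrix "
                             f"{self.omic_name!r}") from exc
        return OmicMatrix(self.omic_name, list(sample_ids),
                          self.feature_genes, self.values[:, cols])


@dataclass
class ClassLabels:
    """Sample-to-class assignment for a two-class comparison.

    ``positive_class`` fixes the orientation of classifier scores and AUC; by
    default it is the lexicographically second of the two labels. Empirical
    P values are computed against a null built under the same orientation, so
    the choice does not affect significance.
    """

    assignments: dict[str, str]
    positive_class: str

    def __post_init__(self) -> None:
        classes = sorted(set(self.assignments.values()))
        if len(classes) != 2:
            raise InputError(
                f"exactly two classes required, found {len(classes)}: {classes}")
        if self.positive_class not in classes:
            raise InputError(
                f"positive class {self.positive_class!r} not among labels {classes}")
        for label in classes:
            n = sum(1 for v in self.assignments.values() if v == label)
            if n < 2:
                raise InputError(
                    f"class {label!r} has only {n} sample(s); at least 2 required")

    @property
    def classes(self) -> tuple[str, str]:
        return tuple(sorted(set(self.assignments.values())))  # type: ignore[return-value]

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def restrict(self, sample_ids: Iterable[str]) -> "ClassLabels":
        kept = {s: self.assignments[s] for s in sample_ids}
        return ClassLabels(kept, self.positive_class)

    def binary(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 vector over ``sample_ids``; 1 marks the positive class."""
        return np.array([1 if self.assignments[s] == self.positive_class else 0
                         for s in sample_ids], dtype=int)

    def class_count(self, label: str) -> int:
        return sum(1 for v in self.assignments.values() if v == label)

    @property
    def min_class_size(self) -> int:
        a, b = self.classes
        return min(self.class_count(a), self.class_count(b))


@dataclass(frozen=True)
class GeneSet:
    name: str
    descriptor: str
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class GeneSetResult:
    """Final per-gene-set scoring: classification AUC, empirical P, BH FDR."""

    set_name: str
    n_genes_annotated: int
    n_features_used: int
    auc: float
    p_value: float
    fdr: float


def _expand_pattern(path_or_pattern: str) -> list[str]:
    if glob.has_magic(path_or_pattern):
        matches = sorted(glob.glob(path_or_pattern))
        if not matches:
            raise InputError(f"no file matches pattern {path_or_pattern!r}")
        return matches
    if not Path(path_or_pattern).exists():
        raise InputError(f"input file not found: {path_or_pattern}")
    return [path_or_pattern]


def _parse_matrix_file(path: str, missing_token: str) -> OmicMatrix:
    with open(path) as handle:
        lines = handle.read().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise InputError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(lines) == 1:
        raise InputError(f"{path}: no features (header-only file)")

    first = lines[1].split("\t")
    # Header may list only sample ids, or carry a leading gene-column label.
    if len(first) == len(header) + 1:
        sample_ids = header
    elif len(first) == len(header) and len(header) >= 2:
        sample_ids = header[1:]
    else:
        raise InputError(
            f"{path}, line 2: expected {len(header)} or {len(header) + 1} "
            f"fields, found {len(first)}")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise InputError(f"{path}: duplicate sample identifier(s): {dupes}")

    n_samples = len(sample_ids)
    genes: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_samples + 1:
            raise InputError(
                f"{path}, line {lineno}: expected {n_samples + 1} fields, "
                f"found {len(fields)}")
        gene = fields[0]
        if not gene:
            raise InputError(f"{path}, line {lineno}: empty gene name")
        row = np.empty(n_samples)
        for j, cell in enumerate(fields[1:]):
            if cell == missing_token:
                row[j] = np.nan
            else:
                try:
                    row[j] = float(cell)
                except ValueError:
                    raise InputError(
                        f"{path}, line {lineno}: non-numeric value {cell!r} "
                        f"for sample {sample_ids[j]!r}") from None
        genes.append(gene)
        rows.append(row)

    values = np.vstack(rows)
    feature_genes = np.array(genes, dtype=object)

    # Classifier input must be complete: drop any feature with a missing value.
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%s: dropped %d feature(s) with missing values",
                    path, n_dropped)
        values = values[complete]
        feature_genes = feature_genes[complete]
    if values.shape[0] == 0:
        raise InputError(f"{path}: no features remain after removing "
                         "missing-value rows")
    if not np.isfinite(values).all():
        raise InputError(f"{path}: non-finite values present")
    return OmicMatrix(Path(path).stem, sample_ids, feature_genes, values)


def read_omic_matrix(path_or_pattern: str,
                     missing_token: str = DEFAULT_MISSING_TOKEN
                     ) -> list[OmicMatrix]:
    """Read one matrix file, or every file matching a wildcard pattern.

    Returns one :class:`OmicMatrix` per matched file; the omic name is the
    file stem. Features containing the missing-value token are dropped (the
    count is logged).
    """
    return [_parse_matrix_file(p, missing_token)
            for p in _expand_pattern(path_or_pattern)]


def read_class_file(path: str, positive_class: str | None = None) -> ClassLabels:
    """Read the two-column sample/class file.

    ``positive_class`` overrides the default orientation (the lexicographically
    second label).
    """
    assignments: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise InputError(
                    f"{path}, line {lineno}: expected 2 tab-separated fields, "
                    f"found {len(fields)}")
            sample, label = fields
            if sample in assignments:
                raise InputError(f"{path}, line {lineno}: duplicate sample "
                                 f"{sample!r}")
            assignments[sample] = label
    if not assignments:
        raise InputError(f"{path}: empty class file")
    labels = sorted(set(assignments.values()))
    if len(labels) != 2:
        raise InputError(f"{path}: exactly two classes required, found "
                         f"{len(labels)}: {labels}")
    return ClassLabels(assignments, positive_class or labels[1])


def read_gmt(path: str) -> GeneSetCollection:
    """Read gene sets in GMT format (set name, descriptor, member genes)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}, line {lineno}: GMT rows need at least 3 fields "
                    f"(name, descriptor, >=1 gene), found {len(fields)}")
            name, descriptor = fields[0], fields[1]
            if name in seen:
                raise InputError(f"{path}, line {lineno}: duplicate gene set "
                                 f"name {name!r}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise InputError(f"{path}, line {lineno}: gene set {name!r} "
                                 "is empty")
            sets.append(GeneSet(name, descriptor, genes))
    if not sets:
        raise InputError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def sort_results(results: Iterable[GeneSetResult]) -> list[GeneSetResult]:
    """Rank order: ascending P, ties by descending AUC, then set name."""
    return sorted(results, key=lambda r: (r.p_value, -r.auc, r.set_name))


def results_frame(results: Iterable[GeneSetResult]) -> pd.DataFrame:
    rows = [(r.set_name, r.n_genes_annotated, r.n_features_used,
             r.auc, r.p_value, r.fdr) for r in sort_results(results)]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Iterable[GeneSetResult], path: str) -> None:
    """Write the rank-ordered result table (tab-delimited with header)."""
    frame = results_frame(results)
    try:
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    except OSError as exc:
        raise InputError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str) -> list[GeneSetResult]:
    """Read back a table produced by :func:`write_results`."""
    frame = pd.read_csv(path, sep="\t")
    return [GeneSetResult(str(r.gene_set), int(r.n_genes), int(r.n_features),
                          float(r.AUC), float(r.p_value), float(r.FDR))
            for r in frame.itertuples(index=False)]


def write_omic_matrix(matrix: OmicMatrix, path: str) -> None:
    """Write a matrix in the tab-delimited input format (round-trippable)."""
    with open(path, "w") as handle:
        handle.write("\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.feature_genes, matrix.values):
            handle.write(gene + "\t" + "\t".join("%.10g" % v for v in row) + "\n")


def write_class_file(labels: ClassLabels, path: str) -> None:
    with open(path, "w") as handle:
        for sample, label in labels.assignments.items():
            handle.write(f"{sample}\t{label}\n")


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as handle:
        for gene_set in collection:
            genes = "\t".join(sorted(gene_set.genes))
            handle.write(f"{gene_set.name}\t{gene_set.descriptor}\t{genes}\n")
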