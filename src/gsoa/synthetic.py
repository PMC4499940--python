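"""Simulated two-class omic datasets with known signal and null gene sets.

The generator emulates a bulk expression study: a samples-by-genes Gaussian
background, plus designated "signal" gene blocks whose members (i) differ in
mean between the two classes and (ii) are mutually correlated (equicorrelated
Gaussian block), since co-regulated pathway genes are not independent. The
between-class shift alternates in sign from gene to gene by default, so a
signal set carries a multidirectional pattern — some genes up, some down —
which set-level mean-shift tests struggle with but a multivariate classifier
can exploit. Gene sets are non-overlapping so the truth table is unambiguous.

Scoring utilities turn a result table plus the generating truth into
confusion counts, sensitivity, specificity and the Matthews Correlation
Coefficient at a series of significance thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, GsoaError
from .io import ClassLabels, GeneSet, GeneSetCollection, GeneSetResult, OmicMatrix

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulated dataset.

    ``class_split`` is the proportion of samples in class 1 (0.5 balanced,
    0.9 for a 90/10 imbalance). ``signal_sets`` lists (set size, number of
    signal genes in the set); the remaining members are background genes.
    ``effect_size`` is the between-class mean shift in units of the
    within-class SD (``noise_sd``); ``dependence`` is the pairwise correlation
    within each signal block. The defaults mirror a 100-sample, 20,000-gene
    expression study with a subtle (1 SD) correlated signal.
    """

    n_samples: int = 100
    n_genes: int = 20_000
    class_split: float = 0.5
    signal_sets: tuple[tuple[int, int], ...] = tuple([(50, 10)] * 20)
    n_null_sets: int = 40
    null_set_size: int = 50
    effect_size: float = 1.0
    dependence: float = 0.3
    noise_sd: float = 1.0
    unidirectional: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_split < 1:
            raise ConfigError("class_split must lie strictly between 0 and 1")
        if not 0 <= self.dependence < 1:
            raise ConfigError("dependence must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        for size, n_sig in self.signal_sets:
            if n_sig > size:
                raise ConfigError(
                    f"signal genes ({n_sig}) exceed set size ({size})")
            if size < 1 or n_sig < 1:
                raise ConfigError("set size and signal count must be >= 1")
        total = (sum(size for size, _ in self.signal_sets)
                 + self.n_null_sets * self.null_set_size)
        if total > self.n_genes:
            raise ConfigError(
                f"gene sets require {total} distinct genes but only "
                f"{self.n_genes} are simulated")


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset: which sets and genes carry signal."""

    set_is_signal: dict[str, bool]
    gene_is_signal: dict[str, bool]
    gene_owner: dict[str, str | None]

    @property
    def signal_sets(self) -> list[str]:
        return [s for s, flag in self.set_is_signal.items() if flag]

    @property
    def null_sets(self) -> list[str]:
        return [s for s, flag in self.set_is_signal.items() if not flag]


@dataclass
class ThresholdMetrics:
    """Confusion counts over gene sets at one significance threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 0.0

    @property
    def mcc(self) -> float:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        if denom == 0:
            return 0.0
        return (tp * tn - fp * fn) / denom


def _equicorrelated_block(rng: np.random.Generator, n_genes: int,
                          n_samples: int, rho: float, sd: float) -> np.ndarray:
    """Unit-SD Gaussian block with pairwise correlation rho, scaled by sd.

    One-factor construction: x_g = sqrt(rho) * z + sqrt(1-rho) * e_g with a
    shared z per sample, which yields exactly the equicorrelation structure.
    """
    z = rng.standard_normal(n_samples)
    e = rng.standard_normal((n_genes, n_samples))
    return sd * (math.sqrt(rho) * z[None, :] + math.sqrt(1.0 - rho) * e)


def generate_dataset(design: SimulationDesign
                     ) -> tuple[OmicMatrix, ClassLabels, GeneSetCollection,
                                TruthTable]:
    """Generate a matrix, class labels, gene sets and truth from one design.

    Fully reproducible from ``design.seed``. Class labels are ``class1`` /
    ``class2`` (class 2, the lexicographically second and thus the positive
    class, receives the mean shift).
    """
    rng = np.random.default_rng(design.seed)
    n, g = design.n_samples, design.n_genes

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    n_class1 = round(design.class_split * n)
    if n_class1 < 2 or n - n_class1 < 2:
        raise ConfigError("each class needs at least 2 samples")
    assignments = {s: ("class1" if i < n_class1 else "class2")
                   for i, s in enumerate(sample_ids)}
    labels = ClassLabels(assignments, positive_class="class2")
    shifted = np.arange(n) >= n_class1  # class2 columns carry the shift

    gene_names = np.array([f"G{i + 1:06d}" for i in range(g)], dtype=object)
    values = rng.normal(0.0, design.noise_sd, size=(g, n))

    sets: list[GeneSet] = []
    set_is_signal: dict[str, bool] = {}
    gene_is_signal = {name: False for name in gene_names}
    gene_owner: dict[str, str | None] = {name: None for name in gene_names}

    cursor = 0
    delta = design.effect_size * design.noise_sd
    for k, (size, n_sig) in enumerate(design.signal_sets):
        members = gene_names[cursor:cursor + size]
        cursor += size
        block = _equicorrelated_block(rng, n_sig, n, design.dependence,
                                      design.noise_sd)
        signs = (np.ones(n_sig) if design.unidirectional
                 else (-1.0) ** np.arange(n_sig))
        block[:, shifted] += (signs * delta)[:, None]
        values[cursor - size:cursor - size + n_sig] = block
        name = f"SIGNAL_SET_{k + 1:03d}"
        sets.append(GeneSet(name, "synthetic signal set",
                            frozenset(members.tolist())))
        set_is_signal[name] = True
        for j, gene in enumerate(members):
            gene_owner[gene] = name
            if j < n_sig:
                gene_is_signal[gene] = True

    for k in range(design.n_null_sets):
        members = gene_names[cursor:cursor + design.null_set_size]
        cursor += design.null_set_size
        name = f"NULL_SET_{k + 1:03d}"
        sets.append(GeneSet(name, "synthetic null set",
                            frozenset(members.tolist())))
        set_is_signal[name] = False
        for gene in members:
            gene_owner[gene] = name

    matrix = OmicMatrix("sim", sample_ids, gene_names, values)
    truth = TruthTable(set_is_signal, gene_is_signal, gene_owner)
    return matrix, labels, GeneSetCollection(sets), truth


def evaluate_thresholds(results: Sequence[GeneSetResult], truth: TruthTable,
                        thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                        use_fdr: bool = True) -> list[ThresholdMetrics]:
    """Score a result table against the truth at each significance threshold.

    A set is called significant when its FDR (or P value, with
    ``use_fdr=False``) is at or below the threshold. Sets the method skipped
    (no feature overlap) count as not called, i.e. misses if they carry
    signal.
    """
    for r in results:
        if r.set_name not in truth.set_is_signal:
            raise GsoaError(f"gene set {r.set_name!r} absent from the truth "
                            "table")
    n_signal = len(truth.signal_sets)
    n_null = len(truth.null_sets)
    out = []
    for t in thresholds:
        called = {r.set_name for r in results
                  if (r.fdr if use_fdr else r.p_value) <= t}
        tp = sum(1 for s in truth.signal_sets if s in called)
        fp = sum(1 for s in truth.null_sets if s in called)
        out.append(ThresholdMetrics(threshold=float(t), tp=tp, fp=fp,
                                    tn=n_null - fp, fn=n_signal - tp))
    return out
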