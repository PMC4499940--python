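"""Empirical significance for gene-set AUC values.

Raw AUCs are biased upward for large gene sets (more features give the SVM
more opportunity to separate the classes even on noise), so AUCs are compared
against a null distribution built from *random* gene sets of matched size.
To bound the computation, sizes are rounded up to a fixed grid of bins; every
actual gene set mapped to a bin is compared against the identical null sample
for that bin, making P values comparable within a bin.

The empirical P value uses the standard permutation convention
``p = (r + 1) / (n + 1)`` where ``r`` counts null AUCs strictly greater than
the observed AUC: the pseudocount keeps P strictly positive, and its floor
``1/(n+1)`` shrinks as the per-bin repeat count ``n`` grows. Benjamini-
Hochberg step-up adjustment converts P values to FDRs.

Per-omic result tables can be combined across omic types by a Monte-Carlo
mean-rank statistic: each table's gene sets are ranked by P value, a set's
statistic is its mean rank across tables, and the combined P is the lower-tail
probability of that mean rank when every table's ranking is an independent
uniform permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import ClassifierConfig, evaluate_gene_set
from .errors import ConfigError, GsoaError, InputError
from .io import ClassLabels, GeneSetResult, OmicMatrix

#: the fixed grid of null gene-set sizes; anything above the last is capped
SIZE_BINS = (1, 5, 10, 25, 50, 75, 100, 125, 150, 200, 250, 300, 400, 500)

DEFAULT_NULL_REPEATS = 100
DEFAULT_COMBINE_PERMUTATIONS = 10_000


def size_bin(n_genes: int) -> int:
    """Round a gene-set size up to the smallest grid bin that holds it.

    Sizes beyond the largest bin map to that bin (the "500+" bucket).
    """
    if n_genes < 1:
        raise GsoaError(f"gene-set size must be >= 1, got {n_genes}")
    for b in SIZE_BINS:
        if n_genes <= b:
            return b
    return SIZE_BINS[-1]


@dataclass
class NullDistributionTable:
    """Per-bin null AUC samples from randomly drawn gene sets."""

    aucs: dict[int, np.ndarray] = field(default_factory=dict)
    repeats: int = DEFAULT_NULL_REPEATS
    seed: int = 0

    def null_for(self, bin_size: int) -> np.ndarray:
        try:
            return self.aucs[bin_size]
        except KeyError:
            raise GsoaError(f"no null distribution built for bin {bin_size}"
                            ) from None


def build_null_table(matrices: Sequence[OmicMatrix], labels: ClassLabels,
                     needed_bins: Iterable[int], cfg: ClassifierConfig,
                     repeats: int = DEFAULT_NULL_REPEATS,
                     seed: int | None = None) -> NullDistributionTable:
    """Evaluate ``repeats`` random gene sets for every needed bin size.

    Gene names are drawn uniformly without replacement from the genes present
    in the loaded data; each draw takes *all* matching feature rows from every
    omic type, mirroring how actual gene sets are handled. Cross-validation
    uses the same :class:`ClassifierConfig` as the actual sets, so null and
    observed AUCs are directly comparable.
    """
    if repeats < 1:
        raise ConfigError(f"null repeats must be >= 1, got {repeats}")
    universe = sorted(set().union(*(m.genes for m in matrices)))
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    table = NullDistributionTable(repeats=repeats, seed=seed)
    for bin_size in sorted(set(needed_bins)):
        if bin_size not in SIZE_BINS:
            raise GsoaError(f"{bin_size} is not a recognized size bin")
        if bin_size > len(universe):
            raise InputError(
                f"null bin size {bin_size} exceeds the {len(universe)} genes "
                "available in the data")
        aucs = np.empty(repeats)
        for r in range(repeats):
            genes = frozenset(rng.choice(universe, size=bin_size,
                                         replace=False).tolist())
            aucs[r], _ = evaluate_gene_set(matrices, labels, genes, cfg)
        table.aucs[bin_size] = aucs
    return table


def empirical_pvalue(auc: float, null_aucs: np.ndarray | Sequence[float]) -> float:
    """Upper-tail empirical P with a +1 pseudocount.

    Counts null AUCs strictly greater than the observed value (ties do not
    count against the set); the result lies in (0, 1].
    """
    null = np.asarray(null_aucs, dtype=float)
    if null.size == 0:
        raise GsoaError("null distribution is empty")
    return float((np.sum(null > auc) + 1) / (null.size + 1))


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    q_i = min_{j >= i} (p_(j) * m / j), capped at 1; tied P values share an
    adjusted value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise GsoaError("P values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class CombinedResult:
    """One gene set's evidence combined across omic types."""

    set_name: str
    per_omic_p: dict[str, float]
    mean_rank: float
    combined_p: float
    combined_fdr: float


def combine_rank_pvalues(
        per_omic_tables: Mapping[str, Sequence[GeneSetResult]],
        permutations: int = DEFAULT_COMBINE_PERMUTATIONS,
        seed: int = 0) -> list[CombinedResult]:
    """Combine per-omic result tables by a seeded Monte-Carlo mean-rank test.

    Only gene sets present in every table are combined (sets skipped on any
    platform are excluded rather than penalized); ranks use average-tie
    handling. The null draws, for each table independently, a uniform random
    rank in 1..m; the combined P counts null mean ranks strictly below the
    observed one, with a +1 pseudocount.
    """
    if len(per_omic_tables) < 2:
        raise ConfigError("rank combination requires at least 2 result tables")
    name_sets = [set(r.set_name for r in tbl)
                 for tbl in per_omic_tables.values()]
    common = sorted(set.intersection(*name_sets))
    if not common:
        raise InputError("result tables share no gene set names")
    n_tables = len(per_omic_tables)
    m = len(common)

    ranks = {}
    pvals = {}
    for omic, tbl in per_omic_tables.items():
        p_by_name = {r.set_name: r.p_value for r in tbl}
        p = np.array([p_by_name[name] for name in common])
        ranks[omic] = rankdata(p, method="average")
        pvals[omic] = p
    mean_ranks = np.mean([ranks[o] for o in per_omic_tables], axis=0)

    rng = np.random.default_rng(seed)
    # marginal null for one set: mean of n_tables iid uniform ranks in 1..m
    null = rng.integers(1, m + 1,
                        size=(permutations, n_tables)).mean(axis=1)
    combined_p = np.array(
        [(np.sum(null < mr) + 1) / (permutations + 1) for mr in mean_ranks])
    combined_fdr = bh_fdr(combined_p)

    results = [
        CombinedResult(
            set_name=name,
            per_omic_p={o: float(pvals[o][i]) for o in per_omic_tables},
            mean_rank=float(mean_ranks[i]),
            combined_p=float(combined_p[i]),
            combined_fdr=float(combined_fdr[i]),
        )
        for i, name in enumerate(common)
    ]
    results.sort(key=lambda r: (r.combined_p, r.mean_rank, r.set_name))
    return results
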