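"""Per-gene-set classification: subset, standardize, cross-validate, score.

For each gene set the data are filtered to the set's genes, samples are
predicted by stratified k-fold cross-validation with an RBF-kernel soft-margin
SVM, and pooled out-of-fold decision values are summarized as the area under
the ROC curve. A high AUC means the set's measurements carry a multivariate,
possibly multidirectional pattern that separates the two classes; an AUC near
0.5 means chance-level prediction.

Standardization (mean centering, unit variance) is fitted on each training
partition only and applied to the held-out fold, so no information leaks from
test samples into the scaler. When several omic matrices are supplied, their
features are concatenated into one feature space (each omic contributes
whichever of the set's genes it measures) and a single SVM is trained on the
samples measured on all omic types.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigError, GsoaError, InputError, NoFeatureOverlap
from .io import ClassLabels, OmicMatrix

#: sentinel: gamma = 1 / number of features of the current submatrix
GAMMA_BY_FEATURES = "scale-by-feature-count"

DEFAULT_TUNE_COSTS = (0.01, 0.1, 1.0, 10.0, 100.0)
#: multipliers applied to 1/n_features when tuning gamma
DEFAULT_TUNE_GAMMA_FACTORS = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings for the cross-validated SVM.

    ``gamma`` may be a positive number or the :data:`GAMMA_BY_FEATURES`
    sentinel (default), which resolves to 1/n_features of each submatrix.
    ``balanced_weights`` applies class-frequency-inverse misclassification
    weights, counteracting class imbalance in the SVM objective. ``seed``
    drives fold shuffling (and, through callers, null-set sampling).
    """

    k_folds: int = 5
    cost: float = 1.0
    gamma: float | str = GAMMA_BY_FEATURES
    tune: bool = False
    tune_costs: tuple[float, ...] = DEFAULT_TUNE_COSTS
    tune_gamma_factors: tuple[float, ...] = DEFAULT_TUNE_GAMMA_FACTORS
    balanced_weights: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigError(f"k_folds must be >= 2, got {self.k_folds}")
        if self.cost <= 0:
            raise ConfigError(f"cost must be positive, got {self.cost}")
        if isinstance(self.gamma, str):
            if self.gamma != GAMMA_BY_FEATURES:
                raise ConfigError(f"unknown gamma sentinel {self.gamma!r}")
        elif self.gamma <= 0:
            raise ConfigError(f"gamma must be positive, got {self.gamma}")

    def resolve_gamma(self, n_features: int) -> float:
        if isinstance(self.gamma, str):
            return 1.0 / n_features
        return float(self.gamma)


@dataclass
class FeatureSubmatrix:
    """A gene set's features across all omic types, aligned to one sample order.

    ``feature_ids`` entries are (omic_name, source row index, gene name).
    ``X`` is samples x features, ready for the classifier.
    """

    feature_ids: list[tuple[str, int, str]]
    X: np.ndarray
    sample_ids: list[str]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_genes(self) -> int:
        """Distinct gene names among the retained features."""
        return len({g for _, _, g in self.feature_ids})


@dataclass
class DecisionScores:
    """One out-of-fold decision value per sample, plus its fold assignment."""

    values: np.ndarray
    folds: np.ndarray
    sample_ids: list[str]


def intersect_samples(matrices: Sequence[OmicMatrix], labels: ClassLabels,
                      k_folds: int = 2) -> tuple[list[OmicMatrix], ClassLabels]:
    """Restrict to samples measured on every omic type and present in the
    class file, preserving the first matrix's sample order.

    Raises if the intersection leaves either class with fewer than ``k_folds``
    members (stratified CV would be impossible at that k).
    """
    if not matrices:
        raise InputError("at least one omic matrix is required")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    common &= set(labels.assignments)
    ordered = [s for s in matrices[0].sample_ids if s in common]
    if not ordered:
        raise InputError("no sample is shared by all omic matrices and the "
                         "class file")
    dropped = sorted(set().union(*(m.sample_ids for m in matrices)) - common)
    if dropped:
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d sample(s) absent from the class file or from some "
            "omic type", len(dropped))
    kept_labels = labels.restrict(ordered)
    for cls in kept_labels.classes:
        n = kept_labels.class_count(cls)
        if n < k_folds:
            raise InputError(
                f"after sample intersection, class {cls!r} has {n} sample(s) "
                f"but k_folds={k_folds}; rerun with k <= {n}" if n >= 2 else
                f"after sample intersection, class {cls!r} has {n} sample(s); "
                "at least 2 per class are required")
    aligned = [m.restrict_samples(ordered) for m in matrices]
    return aligned, kept_labels


def subset_to_gene_set(matrices: Sequence[OmicMatrix],
                       genes: frozenset[str] | set[str]) -> FeatureSubmatrix:
    """Concatenate, across omic types, every feature row annotated to a gene
    in ``genes``. Matrices must already share an identical sample order.

    Raises :class:`NoFeatureOverlap` when no matrix contains any set gene.
    """
    sample_ids = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != sample_ids:
            raise GsoaError("matrices must be sample-aligned before subsetting "
                            "(call intersect_samples first)")
    feature_ids: list[tuple[str, int, str]] = []
    blocks: list[np.ndarray] = []
    for m in matrices:
        mask = np.fromiter((g in genes for g in m.feature_genes),
                           dtype=bool, count=m.n_features)
        idx = np.nonzero(mask)[0]
        if idx.size:
            feature_ids.extend((m.omic_name, int(i), m.feature_genes[i])
                               for i in idx)
            blocks.append(m.values[idx])
    if not blocks:
        raise NoFeatureOverlap("no features in the data map to this gene set")
    X = np.vstack(blocks).T  # samples x features
    return FeatureSubmatrix(feature_ids, np.ascontiguousarray(X),
                            list(sample_ids))


def standardize(train: np.ndarray, test: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray | None]:
    """Mean-center and scale to unit variance, per feature.

    Statistics come from ``train`` rows only (population SD, i.e. divide by n)
    and are applied unchanged to ``test``. Zero-variance features map to
    all-zeros in both partitions.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0)  # ddof=0: population convention
    safe_sd = np.where(sd > 0, sd, 1.0)
    scaled_train = (train - mean) / safe_sd
    scaled_train[:, sd == 0] = 0.0
    if test is None:
        return scaled_train, None
    scaled_test = (test - mean) / safe_sd
    scaled_test[:, sd == 0] = 0.0
    return scaled_train, scaled_test


def _fit_and_score(X_train: np.ndarray, y_train: np.ndarray,
                   X_test: np.ndarray, cost: float, gamma: float,
                   balanced: bool) -> np.ndarray:
    X_tr, X_te = standardize(X_train, X_test)
    svc = SVC(kernel="rbf", C=cost, gamma=gamma,
              class_weight="balanced" if balanced else None)
    svc.fit(X_tr, y_train)
    # decision_function is oriented so larger values favor class 1 (positive)
    return svc.decision_function(X_te)


def tune_parameters(X: np.ndarray, y: np.ndarray,
                    cfg: ClassifierConfig) -> tuple[float, float]:
    """Inner-CV grid search over (cost, gamma) maximizing pooled inner AUC.

    The gamma grid is ``tune_gamma_factors`` x (1/n_features). Ties are broken
    toward the smaller cost, then the smaller gamma, so selection is
    deterministic for a given seed.
    """
    if not cfg.tune_costs or not cfg.tune_gamma_factors:
        raise ConfigError("tuning grid must be non-empty")
    n_features = X.shape[1]
    base_gamma = 1.0 / n_features
    counts = np.bincount(y, minlength=2)
    inner_k = min(cfg.k_folds, int(counts.min()))
    if inner_k < 2:
        raise ConfigError("cannot tune: a class has fewer than 2 training "
                          "samples")
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True,
                          random_state=cfg.seed % (2 ** 31))
    splits = list(skf.split(X, y))
    best: tuple[float, float, float] | None = None  # (-auc, cost, gamma)
    for cost, factor in product(sorted(cfg.tune_costs),
                                sorted(cfg.tune_gamma_factors)):
        gamma = factor * base_gamma
        scores = np.empty(len(y))
        for train_idx, test_idx in splits:
            scores[test_idx] = _fit_and_score(
                X[train_idx], y[train_idx], X[test_idx],
                cost, gamma, cfg.balanced_weights)
        auc = roc_auc_score(y, scores)
        key = (-auc, cost, gamma)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[1], best[2]


def cross_validated_scores(sub: FeatureSubmatrix, labels: ClassLabels,
                           cfg: ClassifierConfig) -> DecisionScores:
    """Out-of-fold RBF-SVM decision values via stratified k-fold CV.

    Every sample is scored exactly once by a model that never saw it during
    training. Fold assignment is deterministic given ``cfg.seed``. With
    ``cfg.tune`` enabled, (cost, gamma) are re-selected per outer training
    partition by nested CV.
    """
    y = labels.binary(sub.sample_ids)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.k_folds:
        raise InputError(
            f"k_folds={cfg.k_folds} exceeds the smaller class size "
            f"({int(counts.min())}); choose k <= {int(counts.min())}")
    gamma = cfg.resolve_gamma(sub.n_features)
    skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True,
                          random_state=cfg.seed % (2 ** 31))
    scores = np.empty(len(y))
    folds = np.full(len(y), -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(sub.X, y)):
        if len(np.unique(y[train_idx])) < 2:  # unreachable under stratification
            raise GsoaError("training fold contains a single class")
        cost, g = (cfg.cost, gamma)
        if cfg.tune:
            cost, g = tune_parameters(sub.X[train_idx], y[train_idx], cfg)
        scores[test_idx] = _fit_and_score(
            sub.X[train_idx], y[train_idx], sub.X[test_idx],
            cost, g, cfg.balanced_weights)
        folds[test_idx] = fold
    assert (folds >= 0).all()
    return DecisionScores(scores, folds, list(sub.sample_ids))


def compute_auc(scores: DecisionScores, labels: ClassLabels) -> float:
    """Area under the ROC of pooled out-of-fold scores.

    Equals the Mann-Whitney probability that a random positive sample scores
    above a random negative one, with ties counted one half.
    """
    y = labels.binary(scores.sample_ids)
    if len(np.unique(y)) < 2:
        raise GsoaError("both classes must be present to compute an AUC")
    return float(roc_auc_score(y, scores.values))


def evaluate_gene_set(matrices: Sequence[OmicMatrix], labels: ClassLabels,
                      genes: frozenset[str] | set[str],
                      cfg: ClassifierConfig) -> tuple[float, int]:
    """Full per-set evaluation: subset -> cross-validate -> AUC.

    Returns (auc, number of feature rows used). Raises
    :class:`NoFeatureOverlap` when the set shares no gene with the data.
    """
    sub = subset_to_gene_set(matrices, genes)
    scores = cross_validated_scores(sub, labels, cfg)
    return compute_auc(scores, labels), sub.n_features


__all__ = [
    "GAMMA_BY_FEATURES", "ClassifierConfig", "FeatureSubmatrix",
    "DecisionScores", "intersect_samples", "subset_to_gene_set",
    "standardize", "tune_parameters", "cross_validated_scores",
    "compute_auc", "evaluate_gene_set",
]
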