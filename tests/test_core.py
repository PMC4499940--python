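"""Classification machinery: subsetting, scaling, CV scoring, AUC, tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsoa import (ClassifierConfig, ClassLabels, ConfigError, InputError,
                  NoFeatureOverlap, OmicMatrix, compute_auc,
                  cross_validated_scores, evaluate_gene_set,
                  intersect_samples, standardize, subset_to_gene_set,
                  tune_parameters)
from gsoa.core import DecisionScores, FeatureSubmatrix

from conftest import make_balanced_labels, make_noise_matrix


def brute_force_auc(pos_scores, neg_scores) -> float:
    """Independent oracle: pairwise win count with ties worth one half."""
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos_scores for n in neg_scores)
    return wins / (len(pos_scores) * len(neg_scores))


def _scores_for(values, labels01):
    samples = [f"S{i}" for i in range(len(values))]
    scores = DecisionScores(np.asarray(values, dtype=float),
                            np.zeros(len(values), dtype=int), samples)
    labels = ClassLabels(
        {s: ("pos" if y else "neg") for s, y in zip(samples, labels01)},
        positive_class="pos")
    return scores, labels


class TestSubsetting:
    def _matrix(self, name, genes, n_samples=4, seed=0):
        rng = np.random.default_rng(seed)
        return OmicMatrix(name, [f"S{i}" for i in range(n_samples)],
                          np.array(genes, dtype=object),
                          rng.standard_normal((len(genes), n_samples)))

    def test_intersection_with_set(self):
        m = self._matrix("expr", ["A", "B", "C"])
        sub = subset_to_gene_set([m], {"B", "C", "D"})
        assert sub.n_features == 2
        assert {g for _, _, g in sub.feature_ids} == {"B", "C"}

    def test_multi_omic_concatenation(self):
        expr = self._matrix("expr", ["A", "B"], seed=1)
        cnv = self._matrix("cnv", ["B", "C"], seed=2)
        sub = subset_to_gene_set([expr, cnv], {"B"})
        assert sub.n_features == 2
        assert [(o, g) for o, _, g in sub.feature_ids] == \
            [("expr", "B"), ("cnv", "B")]

    def test_disjoint_set_raises_skip_status(self):
        m = self._matrix("expr", ["A", "B"])
        with pytest.raises(NoFeatureOverlap):
            subset_to_gene_set([m], {"X", "Y"})


class TestSampleIntersection:
    def _matrix(self, samples, name="m", n_genes=3, seed=0):
        rng = np.random.default_rng(seed)
        return OmicMatrix(name, list(samples),
                          np.array([f"g{i}" for i in range(n_genes)],
                                   dtype=object),
                          rng.standard_normal((n_genes, len(samples))))

    def test_intersection_across_matrices_and_labels(self):
        m1 = self._matrix([f"S{i}" for i in range(1, 6)], "a", seed=1)
        m2 = self._matrix([f"S{i}" for i in range(2, 7)], "b", seed=2)
        labels = ClassLabels({f"S{i}": ("x" if i % 2 else "y")
                              for i in range(1, 7)}, "y")
        aligned, kept = intersect_samples([m1, m2], labels, k_folds=2)
        assert aligned[0].sample_ids == ["S2", "S3", "S4", "S5"]
        assert aligned[1].sample_ids == aligned[0].sample_ids
        assert set(kept.assignments) == {"S2", "S3", "S4", "S5"}

    def test_labels_superset_of_single_matrix(self):
        m = self._matrix(["S1", "S2", "S3", "S4"])
        labels = ClassLabels({f"S{i}": ("x" if i % 2 else "y")
                              for i in range(1, 9)}, "y")
        aligned, kept = intersect_samples([m], labels)
        assert aligned[0].sample_ids == m.sample_ids

    def test_empty_intersection_fatal(self):
        m1 = self._matrix(["S1", "S2"], "a")
        m2 = self._matrix(["S3", "S4"], "b")
        labels = ClassLabels({f"S{i}": ("x" if i % 2 else "y")
                              for i in range(1, 5)}, "y")
        with pytest.raises(InputError, match="no sample"):
            intersect_samples([m1, m2], labels)

    def test_class_smaller_than_k_advises(self):
        m = self._matrix([f"S{i}" for i in range(1, 8)])
        labels = ClassLabels(
            {f"S{i}": ("x" if i <= 2 else "y") for i in range(1, 8)}, "y")
        with pytest.raises(InputError, match="k <= 2"):
            intersect_samples([m], labels, k_folds=5)


class TestStandardize:
    def test_population_sd_convention(self):
        train = np.array([[1.0], [2.0], [3.0]])
        scaled, _ = standardize(train)
        np.testing.assert_allclose(scaled.ravel(),
                                   [-1.2247448714, 0.0, 1.2247448714])

    def test_zero_variance_maps_to_zero(self):
        train = np.full((3, 1), 5.0)
        test = np.array([[7.0]])
        s_train, s_test = standardize(train, test)
        assert (s_train == 0).all() and (s_test == 0).all()

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 4))
        once, _ = standardize(x)
        twice, _ = standardize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_scaler_independent_of_test_partition(self):
        """Leakage guard: perturbing held-out values never changes the scaler."""
        rng = np.random.default_rng(1)
        train = rng.standard_normal((20, 5))
        test_a = rng.standard_normal((5, 5))
        test_b = test_a + 100.0
        s_train_a, s_test_a = standardize(train, test_a)
        s_train_b, s_test_b = standardize(train, test_b)
        np.testing.assert_array_equal(s_train_a, s_train_b)
        # identical transform applied: shifted test shifts by 100/sd exactly
        sd = train.std(axis=0)
        np.testing.assert_allclose(s_test_b - s_test_a,
                                   np.broadcast_to(100.0 / sd, (5, 5)))


class TestComputeAuc:
    @pytest.mark.parametrize("pos,neg,expected", [
        ((2, 3), (0, 1), 1.0),          # perfect ranking
        ((1, 1), (1, 1), 0.5),          # all tied
        ((1, 3), (2, 4), 0.25),         # one win of four pairs
    ])
    def test_frozen_examples_match_oracle(self, pos, neg, expected):
        assert brute_force_auc(pos, neg) == expected
        scores, labels = _scores_for(list(pos) + list(neg),
                                     [1] * len(pos) + [0] * len(neg))
        assert compute_auc(scores, labels) == pytest.approx(expected)

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_oracle_equivalence_on_random_instances(self, data):
        n_pos = data.draw(st.integers(2, 25))
        n_neg = data.draw(st.integers(2, 25))
        values = data.draw(st.lists(
            st.integers(-5, 5), min_size=n_pos + n_neg,
            max_size=n_pos + n_neg))  # small ints force frequent ties
        scores, labels = _scores_for(values, [1] * n_pos + [0] * n_neg)
        expected = brute_force_auc(values[:n_pos], values[n_pos:])
        assert compute_auc(scores, labels) == pytest.approx(expected,
                                                            abs=1e-12)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_label_exchange_mirrors_auc(self, data):
        n_pos = data.draw(st.integers(2, 10))
        n_neg = data.draw(st.integers(2, 10))
        values = data.draw(st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=n_pos + n_neg,
            max_size=n_pos + n_neg))
        scores, labels = _scores_for(values, [1] * n_pos + [0] * n_neg)
        flipped = ClassLabels(labels.assignments, positive_class="neg")
        assert compute_auc(scores, labels) + compute_auc(scores, flipped) \
            == pytest.approx(1.0, abs=1e-12)


class TestCrossValidation:
    def _separable(self, n=20, n_features=10, shift=10.0, seed=3):
        rng = np.random.default_rng(seed)
        genes = np.array([f"g{i}" for i in range(n_features)], dtype=object)
        values = rng.standard_normal((n_features, n))
        values[:, n // 2:] += shift
        m = OmicMatrix("m", [f"S{i:03d}" for i in range(n)], genes, values)
        return m, make_balanced_labels(m.sample_ids)

    def test_separable_classes_fully_ordered(self, default_cfg):
        m, labels = self._separable()
        sub = subset_to_gene_set([m], set(m.feature_genes))
        scores = cross_validated_scores(sub, labels, default_cfg)
        y = labels.binary(scores.sample_ids)
        assert scores.values[y == 1].min() > scores.values[y == 0].max()

    def test_each_sample_scored_once_by_out_of_fold_model(self, default_cfg):
        m, labels = self._separable(n=16)
        sub = subset_to_gene_set([m], set(m.feature_genes))
        scores = cross_validated_scores(sub, labels, default_cfg)
        assert len(scores.values) == 16
        assert set(np.unique(scores.folds)) == set(range(default_cfg.k_folds))

    def test_same_seed_bit_identical(self, default_cfg):
        m, labels = self._separable(shift=1.0)
        sub = subset_to_gene_set([m], set(m.feature_genes))
        a = cross_validated_scores(sub, labels, default_cfg)
        b = cross_validated_scores(sub, labels, default_cfg)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.folds, b.folds)

    def test_k_exceeding_smaller_class_fails_with_guidance(self):
        m, labels = self._separable(n=8)
        sub = subset_to_gene_set([m], set(m.feature_genes))
        with pytest.raises(InputError, match="k <= 4"):
            cross_validated_scores(sub, labels, ClassifierConfig(k_folds=5))

    def test_permuted_labels_on_noise_auc_near_half(self):
        """Monte-Carlo calibration: random labels give chance-level AUC."""
        m = make_noise_matrix(20, 60, seed=11)
        gene_pool = m.feature_genes.tolist()
        rng = np.random.default_rng(12)
        aucs = []
        for rep in range(200):
            perm = rng.permutation(m.n_samples)
            labels = ClassLabels(
                {m.sample_ids[j]: ("a" if i < 30 else "b")
                 for i, j in enumerate(perm)}, "b")
            auc, _ = evaluate_gene_set(
                [m], labels, frozenset(rng.choice(gene_pool, 10,
                                                  replace=False)),
                ClassifierConfig(seed=rep))
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


class TestTuning:
    def test_singleton_grid_matches_fixed_run(self):
        m = make_noise_matrix(8, 24, seed=5)
        labels = make_balanced_labels(m.sample_ids)
        sub = subset_to_gene_set([m], set(m.feature_genes))
        fixed = ClassifierConfig(cost=1.0, gamma=1.0 / 8, seed=5)
        tuned = ClassifierConfig(tune=True, tune_costs=(1.0,),
                                 tune_gamma_factors=(1.0,), seed=5)
        a = cross_validated_scores(sub, labels, fixed)
        b = cross_validated_scores(sub, labels, tuned)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_separable_data_reaches_auc_one(self):
        rng = np.random.default_rng(6)
        genes = np.array([f"g{i}" for i in range(5)], dtype=object)
        values = rng.standard_normal((5, 20))
        values[:, 10:] += 10.0
        m = OmicMatrix("m", [f"S{i:02d}" for i in range(20)], genes, values)
        labels = make_balanced_labels(m.sample_ids)
        auc, _ = evaluate_gene_set([m], labels, set(genes),
                                   ClassifierConfig(tune=True, seed=6))
        assert auc == 1.0

    def test_tie_breaks_toward_smaller_cost_then_gamma(self):
        # widely separated classes: every grid point attains inner AUC 1.0,
        # so the tie must resolve to the smallest cost, then smallest gamma
        rng = np.random.default_rng(13)
        X = rng.standard_normal((24, 3))
        X[12:] += 10.0
        y = np.array([0] * 12 + [1] * 12)
        cfg = ClassifierConfig(tune=True, tune_costs=(10.0, 0.5),
                               tune_gamma_factors=(1.0, 0.1), seed=0)
        cost, gamma = tune_parameters(X, y, cfg)
        assert cost == 0.5
        assert gamma == pytest.approx(0.1 / 3)

    def test_empty_grid_rejected(self):
        cfg = ClassifierConfig(tune=True, tune_costs=(), seed=0)
        with pytest.raises(ConfigError, match="grid"):
            tune_parameters(np.zeros((8, 2)), np.array([0, 1] * 4), cfg)


def test_evaluate_gene_set_deterministic(default_cfg):
    m = make_noise_matrix(30, 40, seed=9)
    labels = make_balanced_labels(m.sample_ids)
    genes = frozenset(m.feature_genes[:12].tolist())
    a = evaluate_gene_set([m], labels, genes, default_cfg)
    b = evaluate_gene_set([m], labels, genes, default_cfg)
    assert a == b


def test_strong_signal_reaches_high_auc():
    rng = np.random.default_rng(21)
    n, n_genes = 100, 200
    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    values = rng.standard_normal((n_genes, n))
    values[:10, 50:] += 2.0  # 10-gene signal at 2 SD
    m = OmicMatrix("m", [f"S{i:03d}" for i in range(n)], genes, values)
    labels = make_balanced_labels(m.sample_ids)
    auc, n_used = evaluate_gene_set([m], labels, set(genes[:10].tolist()),
                                    ClassifierConfig(seed=21))
    assert n_used == 10
    assert auc > 0.9
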