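"""Random-forest training, metric definitions and repeated cross-validation."""

import numpy as np
import pytest

from genecomm.classify import (
    CVConfig,
    RFConfig,
    compute_metrics,
    external_validate,
    pairwise_auc,
    rank_communities,
    repeated_cv,
    train_rf,
)
from genecomm.io import ExpressionMatrix


def brute_force_auc(y, p):
    """Explicit loop over positive/negative pairs with half tie credit."""
    pos = [pi for pi, yi in zip(p, y) if yi == 1]
    neg = [pi for pi, yi in zip(p, y) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestTrainRF:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(6, 1, (40, 5))])
        y = np.repeat([0, 1], 40)
        rf = train_rf(X, y, RFConfig(n_trees=50, seed=0))
        assert (rf.predict(X) == y).mean() >= 0.95

    def test_all_features_mtry_uses_every_feature(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 7))
        y = rng.integers(0, 2, size=30)
        rf = train_rf(X, y, RFConfig(n_trees=5, mtry="all_features", seed=0))
        assert rf.max_features is None

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        p1 = train_rf(X, y, RFConfig(seed=5)).predict_proba(X)
        p2 = train_rf(X, y, RFConfig(seed=5)).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_rf(np.ones((4, 2)), np.zeros(4), RFConfig())


class TestMetrics:
    def test_perfect_probabilities(self):
        m = compute_metrics(np.array([1, 0, 1]), np.array([1.0, 0.0, 1.0]))
        assert m.accuracy == 100.0 and m.auc == 100.0 and m.f1 == 100.0
        assert m.logloss < 1e-10

    def test_hand_computed_four_sample_toy(self):
        # positives at 0.9/0.5, negatives at 0.5/0.1: 3 wins + 1 tie of 4
        # pairs -> AUC 87.5; strict > 0.5 rule -> preds (1,0,0,0):
        # accuracy 75, F1 = 2*1*0.5/1.5 = 66.67
        m = compute_metrics(np.array([1, 1, 0, 0]),
                            np.array([0.9, 0.5, 0.5, 0.1]))
        assert m.accuracy == pytest.approx(75.0)
        assert m.auc == pytest.approx(87.5)
        assert m.f1 == pytest.approx(200.0 / 3.0)

    def test_constant_half_logloss_is_ln2(self):
        m = compute_metrics(np.array([1, 0, 1, 0]), np.full(4, 0.5))
        assert m.logloss == pytest.approx(np.log(2.0))

    def test_auc_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(4, 20)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            assert pairwise_auc(y, p) == pytest.approx(
                brute_force_auc(y, p), abs=1e-12
            )

    def test_metrics_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        m1 = compute_metrics(y, p)
        m2 = compute_metrics(y[perm], p[perm])
        assert m1 == m2

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError, match="one class"):
            compute_metrics(np.ones(3), np.array([0.2, 0.5, 0.9]))


class TestRepeatedCV:
    def _data(self, sep, seed=0, n=100, d=10):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n // 2, d)),
                       rng.normal(sep, 1, (n // 2, d))])
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_separable_data_high_accuracy(self):
        X, y = self._data(3.0)
        rep = repeated_cv(X, y, RFConfig(n_trees=50, seed=0),
                          CVConfig(repeats=3, seed=0))
        assert rep.mean().accuracy >= 95.0

    def test_null_features_auc_near_half(self):
        X, y = self._data(0.0, seed=1, n=200)
        rep = repeated_cv(X, y, RFConfig(n_trees=50, seed=0),
                          CVConfig(repeats=5, seed=1))
        assert 42.0 <= rep.mean().auc <= 58.0

    def test_sd_positive_for_finite_data(self):
        X, y = self._data(1.0, seed=2)
        rep = repeated_cv(X, y, RFConfig(n_trees=30, seed=0),
                          CVConfig(repeats=4, seed=2))
        assert rep.sd().accuracy > 0.0
        assert len(rep.rounds) == 4

    def test_infeasible_stratification_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        y = np.array([1, 1, 1, 1, 1, 1, 0, 0])
        with pytest.raises(ValueError, match="infeasible"):
            repeated_cv(X, y, RFConfig(), CVConfig(k_folds=5))

    def test_determinism(self):
        X, y = self._data(1.5, seed=3)
        r1 = repeated_cv(X, y, RFConfig(n_trees=20, seed=1), CVConfig(repeats=2, seed=7))
        r2 = repeated_cv(X, y, RFConfig(n_trees=20, seed=1), CVConfig(repeats=2, seed=7))
        assert r1.mean() == r2.mean()


class TestRankCommunities:
    class _Rep:
        def __init__(self, acc):
            self._acc = acc

        def mean(self):
            from genecomm.classify import MetricSet

            return MetricSet(self._acc, 0, 0, 0)

    def test_cutoff_and_order(self):
        reports = {"a": self._Rep(95.0), "b": self._Rep(89.0), "c": self._Rep(91.0)}
        ranked = rank_communities(reports, 90.0)
        assert [c for c, _ in ranked] == ["a", "c"]

    def test_empty_input(self):
        assert rank_communities({}, 90.0) == []

    def test_zero_cutoff_returns_all_sorted(self):
        reports = {"a": self._Rep(10.0), "b": self._Rep(50.0)}
        ranked = rank_communities(reports, 0.0)
        assert [c for c, _ in ranked] == ["b", "a"]


class TestExternalValidate:
    def _train_model(self, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (60, 5)), rng.normal(3, 1, (60, 5))])
        y = np.repeat([0, 1], 60)
        model = train_rf(X, y, RFConfig(n_trees=50, seed=0))
        genes = [f"g{i}" for i in range(5)]
        means = {g: float(X[:, j].mean()) for j, g in enumerate(genes)}
        return model, genes, means

    def _test_matrix(self, genes, seed=1, shift=3.0, n_per=100):
        rng = np.random.default_rng(seed)
        vals = np.hstack([rng.normal(0, 1, (len(genes), n_per)),
                          rng.normal(shift, 1, (len(genes), n_per))])
        samples = [f"s{i}" for i in range(2 * n_per)]
        labels = {s: ("normal" if i < n_per else "tumor")
                  for i, s in enumerate(samples)}
        return ExpressionMatrix(list(genes), samples, vals, labels)

    def test_same_law_generalizes(self):
        model, genes, means = self._train_model()
        ext = self._test_matrix(genes)
        m = external_validate(model, genes, ext, means)
        assert m.accuracy >= 90.0

    def test_permuted_labels_null_auc(self):
        model, genes, means = self._train_model()
        ext = self._test_matrix(genes)
        rng = np.random.default_rng(5)
        samples = list(ext.sample_ids)
        shuffled = rng.permutation([ext.labels[s] for s in samples])
        ext_null = ExpressionMatrix(ext.gene_ids, samples, ext.values,
                                    dict(zip(samples, shuffled)))
        m = external_validate(model, genes, ext_null, means)
        assert 40.0 <= m.auc <= 60.0

    def test_missing_genes_imputed_with_warning(self, caplog):
        model, genes, means = self._train_model()
        ext = self._test_matrix(genes[:3])  # 2 of 5 genes absent
        with caplog.at_level("WARNING"):
            m = external_validate(model, genes, ext, means)
        assert any("2/5" in r.message for r in caplog.records)
        assert m.accuracy > 50.0

    def test_zero_overlap_rejected(self):
        model, genes, means = self._train_model()
        ext = self._test_matrix(["x1", "x2"])
        with pytest.raises(ValueError, match="no overlap"):
            external_validate(model, genes, ext, means)
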