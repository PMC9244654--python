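"""Metrics, cross-validation, grid search and input reshaping."""

import numpy as np
import pandas as pd
import pytest

from oncosep.models import (
    ModelConfig,
    ModelConfigError,
    MetricError,
    compute_metrics,
    grid_search,
    make_model,
    reshape_features,
    run_cross_validation,
)


def auroc_by_mann_whitney(y, s):
    """U statistic normalized by n1*n0, ties counted half."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _separable(n=120, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < 0.4).astype(int)
    X[y == 1, 0] += 4.0
    return X, y


class TestMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        m = compute_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert all(v == 1.0 for v in m.values())

    def test_confusion_counts_example(self):
        # TP=2, FP=1, FN=1, TN=6
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.1, 0.7, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2])
        m = compute_metrics(y, s)
        assert m["precision"] == pytest.approx(2 / 3, abs=1e-9)
        assert m["recall"] == pytest.approx(2 / 3, abs=1e-9)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-9)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_constant_scores_auroc_half(self):
        y = np.array([0, 1] * 10)
        m = compute_metrics(y, np.full(20, 0.5))
        assert m["auroc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            compute_metrics(np.ones(5), np.linspace(0, 1, 5))

    def test_f1_identity(self):
        rng = np.random.default_rng(1)
        y = (rng.random(50) < 0.5).astype(int)
        s = rng.random(50)
        m = compute_metrics(y, s)
        if m["precision"] + m["recall"] > 0:
            expected = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert m["f1"] == pytest.approx(expected, abs=1e-12)

    def test_auroc_equals_normalized_u(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(6, 20))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse grid to force ties
            m = compute_metrics(y, s)
            assert m["auroc"] == pytest.approx(auroc_by_mann_whitney(y, s), abs=1e-8)


class TestModelConfig:
    def test_unknown_family_rejected(self):
        with pytest.raises(ModelConfigError):
            ModelConfig(family="svm")

    def test_bad_hyperparameter_rejected(self):
        with pytest.raises(ModelConfigError):
            ModelConfig(family="random_forest", hyperparameters={"kernel": "rbf"})

    def test_zero_trees_rejected(self):
        with pytest.raises(ModelConfigError):
            ModelConfig(family="random_forest", hyperparameters={"n_trees": 0})

    def test_default_forest_has_20_trees(self):
        model = make_model(ModelConfig(family="random_forest"))
        assert model.n_estimators == 20


class TestReshape:
    def test_conv_pads_to_42x42(self):
        X = np.ones((3, 1738))
        out, shape = reshape_features(X, "conv_resnet")
        assert shape == (1, 42, 42)
        assert out.shape == (3, 1764)
        assert (out[:, 1738:] == 0).all()

    def test_conv_too_many_features_rejected(self):
        with pytest.raises(ModelConfigError):
            reshape_features(np.ones((2, 1765)), "conv_resnet")

    def test_flat_family_passthrough(self):
        out, shape = reshape_features(np.ones((5, 4)), "random_forest")
        assert out.shape == (5, 4)
        assert shape == (4,)

    def test_lstm_pads_sequences_to_max_length(self):
        seqs = [np.ones((2, 3)), np.ones((5, 3))]
        out, shape = reshape_features(None, "recurrent_lstm", sequences=seqs)
        assert out.shape == (2, 5, 3)
        assert shape == (5, 3)
        assert (out[0, 2:] == 0).all()

    def test_lstm_flat_table_becomes_length_one_sequence(self):
        out, shape = reshape_features(np.ones((4, 7)), "recurrent_lstm")
        assert out.shape == (4, 1, 7)


class TestCrossValidation:
    def test_separable_data_high_auroc(self):
        X, y = _separable()
        rep = run_cross_validation(X, y, ModelConfig(family="logistic_regression"))
        assert rep.aggregate["auroc"] >= 0.99

    def test_permuted_labels_null_auroc(self):
        """Random labels give chance-level AUROC averaged over seeds."""
        X, y = _separable(n=150)
        aurocs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            cfg = ModelConfig(family="logistic_regression", seed=seed)
            aurocs.append(run_cross_validation(X, yp, cfg).aggregate["auroc"])
        assert 0.4 <= float(np.mean(aurocs)) <= 0.6

    @pytest.mark.parametrize("family", ["logistic_regression", "random_forest"])
    def test_deterministic_given_seed(self, family):
        X, y = _separable(seed=3)
        cfg = ModelConfig(family=family, seed=11)
        r1 = run_cross_validation(X, y, cfg)
        r2 = run_cross_validation(X, y, cfg)
        assert r1.per_fold == r2.per_fold
        assert r1.aggregate == r2.aggregate

    def test_too_few_class_rows_rejected(self):
        X = np.ones((10, 2))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ModelConfigError):
            run_cross_validation(X, y, ModelConfig(family="logistic_regression"))

    def test_aggregate_is_fold_mean(self):
        X, y = _separable(seed=4)
        rep = run_cross_validation(X, y, ModelConfig(family="random_forest"))
        for metric, value in rep.aggregate.items():
            assert value == pytest.approx(np.mean([f[metric] for f in rep.per_fold]))

    def test_training_unaffected_by_test_labels(self):
        """No leakage: fits are identical whatever the held-out labels are."""
        from sklearn.model_selection import StratifiedKFold

        X, y = _separable(seed=5)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        train_idx, test_idx = next(iter(skf.split(X, y)))
        y_shuffled = y.copy()
        y_shuffled[test_idx] = np.random.default_rng(0).permutation(y[test_idx])
        m1 = make_model(ModelConfig(family="random_forest", seed=0)).fit(X[train_idx], y[train_idx])
        m2 = make_model(ModelConfig(family="random_forest", seed=0)).fit(
            X[train_idx], y_shuffled[train_idx]
        )
        p1 = m1.predict_proba(X[test_idx])
        p2 = m2.predict_proba(X[test_idx])
        assert np.array_equal(p1, p2)


class TestNeuralFamiliesSmoke:
    def test_feedforward_learns_separable(self):
        X, y = _separable(n=100)
        cfg = ModelConfig(family="feedforward_net", hyperparameters={"max_iter": 200})
        rep = run_cross_validation(X, y, cfg)
        assert rep.aggregate["auroc"] >= 0.9

    def test_conv_resnet_fits_and_predicts(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 1764))
        y = (rng.random(60) < 0.5).astype(int)
        X[y == 1] += 0.4
        cfg = ModelConfig(
            family="conv_resnet", hyperparameters={"n_epochs": 8, "channels": 2}, seed=0
        )
        rep = run_cross_validation(X, y, cfg, n_folds=2)
        assert set(rep.aggregate) == {"accuracy", "auroc", "auprc", "precision", "recall", "f1"}
        assert rep.aggregate["auroc"] > 0.8

    def test_lstm_fits_and_predicts(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 6))
        y = (rng.random(80) < 0.5).astype(int)
        X[y == 1, 2] += 3.0
        cfg = ModelConfig(family="recurrent_lstm", hyperparameters={"n_epochs": 30}, seed=0)
        rep = run_cross_validation(X, y, cfg, n_folds=2)
        assert rep.aggregate["auroc"] > 0.8


class TestGridSearch:
    def test_singleton_grid_returned(self):
        X, y = _separable()
        best = grid_search(X, y, "random_forest", [{"n_trees": 5}])
        assert best.hyperparameters == {"n_trees": 5}

    def test_sane_config_beats_degenerate(self):
        X, y = _separable(n=150)
        grid = [{"max_depth": 1, "n_trees": 1}, {"n_trees": 20}]
        best = grid_search(X, y, "random_forest", grid, seed=0)
        assert best.hyperparameters == {"n_trees": 20}

    def test_deterministic_given_seed_and_order(self):
        X, y = _separable(seed=6)
        grid = [{"n_trees": 5}, {"n_trees": 10}]
        b1 = grid_search(X, y, "random_forest", grid, seed=2)
        b2 = grid_search(X, y, "random_forest", grid, seed=2)
        assert b1 == b2

    def test_empty_grid_rejected(self):
        with pytest.raises(ModelConfigError):
            grid_search(np.ones((10, 2)), np.array([0, 1] * 5), "random_forest", [])
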