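"""Out-of-fold prediction machinery and greedy ensemble construction."""

import itertools

import numpy as np
import pytest
from sklearn.datasets import make_classification, make_regression
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.linear_model import LogisticRegression, Ridge

from hiascreen.metrics import log_loss, rmse, roc_auc
from hiascreen.modeling import (
    CrossValConfig,
    EnsembleModel,
    cross_val_predict,
    greedy_ensemble_weights,
    predict_proba,
    predict_value,
    train_classifier_ensemble,
    train_regressor_ensemble,
)


class TestCrossValPredict:
    def test_leave_one_out_fold_structure(self):
        X, y = make_classification(
            n_samples=10, n_features=4, n_informative=3, n_redundant=1,
            random_state=0,
        )
        cv = CrossValConfig(k=10, seed=0, stratified=False)
        oof = cross_val_predict(LogisticRegression(max_iter=500), X, y, cv,
                                "classification")
        assert len(oof.values) == 10
        for idx in range(10):
            fold = oof.fold_id[idx]
            assert idx not in oof.train_index_sets[fold]
            assert len(oof.train_index_sets[fold]) == 9

    def test_constant_label_baseline(self):
        X = np.random.default_rng(0).random((12, 3))
        y = np.ones(12)
        cv = CrossValConfig(k=3, seed=0, stratified=False)
        oof = cross_val_predict(DummyClassifier(strategy="prior"), X, y, cv,
                                "classification")
        assert np.allclose(oof.values, 1.0)

    def test_separable_data_high_auc(self):
        X, y = make_classification(
            n_samples=100, n_features=10, n_informative=8, class_sep=3.0,
            random_state=1,
        )
        cv = CrossValConfig(k=10, seed=1)
        oof = cross_val_predict(LogisticRegression(max_iter=2000), X, y, cv,
                                "classification")
        _, auc = roc_auc(y, oof.values)
        assert auc >= 0.95

    def test_oof_purity(self):
        """No sample is predicted by a model that saw it in training."""
        X, y = make_classification(n_samples=40, n_features=5, random_state=2)
        cv = CrossValConfig(k=5, seed=2)
        oof = cross_val_predict(LogisticRegression(max_iter=500), X, y, cv,
                                "classification")
        for idx in range(40):
            assert idx not in oof.train_index_sets[oof.fold_id[idx]]

    def test_stratification_infeasible_raises(self):
        X = np.zeros((10, 2))
        y = np.array([1] * 9 + [0])
        cv = CrossValConfig(k=5, seed=0, stratified=True)
        with pytest.raises(ValueError, match="folds"):
            cross_val_predict(LogisticRegression(), X, y, cv, "classification")

    def test_regression_output_clipped(self):
        X, y = make_regression(n_samples=30, n_features=3, random_state=3)
        y = y * 10  # far outside [0, 100]
        cv = CrossValConfig(k=5, seed=3, stratified=False)
        oof = cross_val_predict(Ridge(), X, y, cv, "regression")
        assert oof.values.min() >= 0 and oof.values.max() <= 100


class TestGreedyEnsemble:
    def test_never_worse_than_best_single_exhaustive(self):
        """Against exhaustive weight search on a 3-candidate toy problem."""
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 50).astype(float)
        oof = {
            "a": np.clip(y * 0.7 + rng.normal(0, 0.2, 50), 0.01, 0.99),
            "b": np.clip(0.5 + rng.normal(0, 0.1, 50), 0.01, 0.99),
            "c": np.clip(y * 0.4 + 0.3 + rng.normal(0, 0.3, 50), 0.01, 0.99),
        }
        weights = greedy_ensemble_weights(oof, y, log_loss)
        blended = sum(w * oof[k] for k, w in weights.items())
        best_single = min(log_loss(y, v) for v in oof.values())
        assert log_loss(y, blended) <= best_single + 1e-12

    def test_weights_sum_to_one_nonnegative(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(0, 100, 30)
        oof = {f"m{i}": rng.uniform(0, 100, 30) for i in range(4)}
        weights = greedy_ensemble_weights(oof, y, rmse)
        assert all(w >= 0 for w in weights.values())
        assert sum(weights.values()) == pytest.approx(1.0)

    def test_perfect_candidate_dominates(self):
        y = np.arange(20, dtype=float)
        oof = {"perfect": y.copy(), "noise": y + 5.0}
        weights = greedy_ensemble_weights(oof, y, rmse)
        assert weights == {"perfect": 1.0}


class TestEnsembleTraining:
    def test_classifier_ensemble_beats_baseline(self, tiny_benchmark):
        cv = CrossValConfig(k=5, seed=0)
        model, oof = train_classifier_ensemble(
            tiny_benchmark["X_train"], tiny_benchmark["y_train"], cv
        )
        _, auc = roc_auc(tiny_benchmark["y_train"], oof.values)
        assert auc >= 0.8  # baseline AUC is 0.5
        assert model.weights.sum() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            train_classifier_ensemble(X, np.ones(10), CrossValConfig(k=2))

    def test_noiseless_linear_regression_recovered(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (60, 1))
        y = 20 + 60 * X[:, 0]  # exactly linear, inside [0, 100]
        cv = CrossValConfig(k=5, seed=6, stratified=False)
        _, oof = train_regressor_ensemble(X, y, cv)
        assert rmse(y, oof.values) <= 0.1 * y.std()

    def test_baseline_regressor_predicts_mean(self):
        rng = np.random.default_rng(7)
        X = rng.random((20, 2))
        y = rng.uniform(0, 100, 20)
        cv = CrossValConfig(k=4, seed=7, stratified=False)
        oof = cross_val_predict(DummyRegressor(strategy="mean"), X, y, cv,
                                "regression")
        # each fold's prediction is that fold's training mean
        for f, train_idx in enumerate(oof.train_index_sets):
            fold_mask = oof.fold_id == f
            assert np.allclose(oof.values[fold_mask], y[train_idx].mean())

    def test_empty_roster_rejected(self):
        X = np.random.default_rng(0).random((20, 2))
        y = np.linspace(0, 100, 20)
        with pytest.raises(ValueError, match="roster"):
            train_regressor_ensemble(
                X, y, CrossValConfig(k=2, stratified=False), candidates={}
            )

    def test_determinism(self):
        X, y = make_classification(n_samples=60, n_features=8, random_state=8)
        cv = CrossValConfig(k=5, seed=8)
        candidates = {
            "lr": LogisticRegression(max_iter=1000),
            "baseline": DummyClassifier(strategy="prior"),
        }
        m1, oof1 = train_classifier_ensemble(X, y, cv, dict(candidates))
        m2, oof2 = train_classifier_ensemble(X, y, cv, dict(candidates))
        assert np.array_equal(oof1.values, oof2.values)
        assert m1.member_names == m2.member_names
        assert np.array_equal(
            predict_proba(m1, X), predict_proba(m2, X)
        )


class TestPrediction:
    def _stub_classifier(self, p):
        class Stub:
            classes_ = [0, 1]

            def predict_proba(self, X):
                return np.column_stack(
                    [np.full(len(X), 1 - p), np.full(len(X), p)]
                )

        return Stub()

    def _stub_regressor(self, v):
        class Stub:
            def predict(self, X):
                return np.full(len(X), v)

        return Stub()

    def test_single_member_identity(self):
        model = EnsembleModel(
            "classification", ["a"], [self._stub_classifier(0.3)], np.array([1.0])
        )
        assert np.allclose(predict_proba(model, np.zeros((4, 2))), 0.3)

    def test_equal_weight_average(self):
        model = EnsembleModel(
            "classification",
            ["a", "b"],
            [self._stub_classifier(0.2), self._stub_classifier(0.8)],
            np.array([0.5, 0.5]),
        )
        assert np.allclose(predict_proba(model, np.zeros((3, 2))), 0.5)

    def test_degenerate_weight_selects_member(self):
        model = EnsembleModel(
            "classification",
            ["a", "b"],
            [self._stub_classifier(0.2), self._stub_classifier(0.8)],
            np.array([1.0, 0.0]),
        )
        assert np.allclose(predict_proba(model, np.zeros((3, 2))), 0.2)

    def test_regression_average_and_clip(self):
        model = EnsembleModel(
            "regression",
            ["a", "b"],
            [self._stub_regressor(80.0), self._stub_regressor(100.0)],
            np.array([0.5, 0.5]),
        )
        assert np.allclose(predict_value(model, np.zeros((2, 2))), 90.0)
        low = EnsembleModel(
            "regression", ["a"], [self._stub_regressor(-5.0)], np.array([1.0])
        )
        assert np.allclose(predict_value(low, np.zeros((2, 2))), 0.0)
        high = EnsembleModel(
            "regression", ["a"], [self._stub_regressor(112.0)], np.array([1.0])
        )
        assert np.allclose(predict_value(high, np.zeros((2, 2))), 100.0)

    def test_task_mismatch(self):
        model = EnsembleModel(
            "regression", ["a"], [self._stub_regressor(1.0)], np.array([1.0])
        )
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((1, 1)))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel(
                "classification", ["a"], [self._stub_classifier(0.5)],
                np.array([0.7]),
            )
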