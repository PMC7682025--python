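import numpy as np
import pandas as pd
import pytest

from metageo.classify import (OvrLogisticModel, evaluate, load_model,
                              predict_city_probabilities, save_model,
                              train_ovr_logistic)
from metageo.discretize import TernaryMatrix


def _ternary(values, taxa=None):
    values = np.asarray(values)
    taxa = taxa or [f"k__K|s__t{j}" for j in range(values.shape[1])]
    return TernaryMatrix([f"s{i}" for i in range(values.shape[0])], taxa, values)


class TestTraining:
    def test_all_zero_features_give_prevalence(self):
        X = _ternary(np.zeros((20, 3), dtype=int))
        y = np.array(["A"] * 5 + ["B"] * 15)
        model = train_ovr_logistic(X, y, l2_strength=1e-6)
        probs = model.sigmoid_scores(np.zeros((1, 3)))
        # intercept-only fit: per-city sigmoid ~ class prevalence
        assert probs[0, model.city_list.index("A")] == pytest.approx(0.25, abs=0.02)
        assert probs[0, model.city_list.index("B")] == pytest.approx(0.75, abs=0.02)

    def test_separable_two_city_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        half = rng.integers(-1, 2, size=(12, 4))
        X = _ternary(np.vstack([np.column_stack([np.ones(12, int), half]),
                                np.column_stack([-np.ones(12, int), half])]))
        y = np.array(["A"] * 12 + ["B"] * 12)
        model = train_ovr_logistic(X, y)
        preds = predict_city_probabilities(model, X)
        acc, _, _ = evaluate(preds, y)
        assert acc == 1.0

    def test_single_city_errors(self):
        with pytest.raises(ValueError, match=">= 2 cities"):
            train_ovr_logistic(_ternary(np.zeros((4, 2), int)), ["A"] * 4)

    def test_sample_order_invariance(self, small_ternary):
        X, y = small_ternary
        model_a = train_ovr_logistic(X, y)
        perm = np.random.default_rng(1).permutation(X.n_samples)
        X_perm = TernaryMatrix([X.sample_ids[i] for i in perm], list(X.taxa),
                               X.values[perm])
        model_b = train_ovr_logistic(X_perm, y[perm])
        np.testing.assert_allclose(model_a.W, model_b.W, atol=1e-5)
        np.testing.assert_allclose(model_a.theta, model_b.theta, atol=1e-5)

    def test_regularization_path_monotone(self, small_ternary):
        X, y = small_ternary
        norms = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            model = train_ovr_logistic(X, y, l2_strength=lam)
            norms.append(np.linalg.norm(model.W, axis=1))
        for weaker, stronger in zip(norms, norms[1:]):
            assert np.all(stronger <= weaker + 1e-8)


class TestPrediction:
    def test_raw_scores_match_direct_formula(self):
        rng = np.random.default_rng(2)
        model = OvrLogisticModel(
            city_list=["A", "B", "C"],
            feature_names=[f"f{j}" for j in range(5)],
            W=rng.normal(size=(3, 5)),
            theta=rng.normal(size=3),
            normalize_output=False,
        )
        X = rng.integers(-1, 2, size=(7, 5)).astype(float)
        probs = predict_city_probabilities(model, X).to_numpy()
        for i in range(7):
            for c in range(3):
                direct = 1.0 / (1.0 + np.exp(-(model.W[c] @ X[i] + model.theta[c])))
                assert probs[i, c] == pytest.approx(direct, abs=1e-12)

    def test_scores_strictly_inside_unit_interval(self):
        model = OvrLogisticModel(["A", "B"], ["f0"], W=np.array([[30.0], [-30.0]]),
                                 theta=np.zeros(2), normalize_output=False)
        probs = predict_city_probabilities(model, np.array([[1.0], [-1.0]]))
        assert np.all(probs.to_numpy() > 0) and np.all(probs.to_numpy() < 1)

    def test_normalized_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        model = OvrLogisticModel(
            ["A", "B", "C", "D"], [f"f{j}" for j in range(6)],
            W=rng.normal(size=(4, 6)), theta=rng.normal(size=4),
            normalize_output=True)
        probs = predict_city_probabilities(model, rng.normal(size=(10, 6)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_symmetric_two_city_gives_half_half(self):
        model = OvrLogisticModel(["A", "B"], ["f0", "f1"],
                                 W=np.array([[1.0, 0.0], [0.0, 1.0]]),
                                 theta=np.zeros(2), normalize_output=True)
        probs = predict_city_probabilities(model, np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(probs.to_numpy(), [[0.5, 0.5]])

    def test_feature_mismatch_errors(self):
        model = OvrLogisticModel(["A", "B"], ["f0"], W=np.ones((2, 1)),
                                 theta=np.zeros(2))
        with pytest.raises(ValueError, match="feature"):
            predict_city_probabilities(model, _ternary(np.zeros((2, 2), int)))


class TestEvaluate:
    def _frame(self, values, cities):
        return pd.DataFrame(values, columns=cities)

    def test_perfect_predictions(self):
        preds = self._frame(np.eye(3), ["A", "B", "C"])
        acc, confusion, ties = evaluate(preds, ["A", "B", "C"])
        assert acc == 1.0
        np.testing.assert_array_equal(confusion.to_numpy(), np.eye(3))
        assert ties == []

    def test_constant_predictor_accuracy(self):
        preds = self._frame(np.tile([0.9, 0.05, 0.03, 0.02], (8, 1)),
                            ["A", "B", "C", "D"])
        truth = ["A", "A", "B", "B", "C", "C", "D", "D"]
        acc, _, _ = evaluate(preds, truth)
        assert acc == 0.25

    def test_tie_goes_to_lexicographic_first(self):
        preds = self._frame([[0.5, 0.5]], ["B", "A"])
        acc, _, ties = evaluate(preds, ["A"])
        assert acc == 1.0  # tie resolved to "A"
        assert len(ties) == 1

    def test_unknown_city_in_truth(self):
        preds = self._frame([[1.0, 0.0]], ["A", "B"])
        with pytest.raises(ValueError, match="unknown"):
            evaluate(preds, ["Z"])


def test_model_serialization_round_trip(tmp_path, small_ternary):
    X, y = small_ternary
    model = train_ovr_logistic(X, y)
    save_model(model, tmp_path / "model.json")
    back = load_model(tmp_path / "model.json")
    np.testing.assert_array_equal(model.W, back.W)
    np.testing.assert_array_equal(model.theta, back.theta)
    assert back.city_list == model.city_list
    assert back.feature_names == model.feature_names
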