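"""One-vs-rest L2-regularized logistic regression over cities.

One binary logistic model is fit per city (that city against all
others), each producing a sigmoid score

    p = 1 / (1 + exp(-(w . x + theta)))

for a sample with feature vector ``x``.  The per-city scores can be
reported raw, or normalized to sum to one across cities — normalization
is the default so that the scores are comparable across cities when
used as kriging anchor values downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .discretize import TernaryMatrix

__all__ = [
    "OvrLogisticModel",
    "train_ovr_logistic",
    "predict_city_probabilities",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass
class OvrLogisticModel:
    """Per-city weight vectors and intercepts of the one-vs-rest model."""

    city_list: list[str]
    feature_names: list[str]
    W: np.ndarray  # (n_cities, n_features)
    theta: np.ndarray  # (n_cities,)
    l2_strength: float = 1.0
    normalize_output: bool = True

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        n_c, n_f = len(self.city_list), len(self.feature_names)
        if self.W.shape != (n_c, n_f) or self.theta.shape != (n_c,):
            raise ValueError("parameter shapes do not match city/feature lists")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.theta))):
            raise ValueError("non-finite model parameters")

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W.T + self.theta

    def sigmoid_scores(self, X: np.ndarray) -> np.ndarray:
        """Raw per-city sigmoid scores, shape (n_samples, n_cities)."""
        z = self.decision(np.asarray(X, dtype=float))
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-z))


def _as_matrix(X: TernaryMatrix | np.ndarray) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(X, TernaryMatrix):
        return X.values.astype(float), list(X.taxa), list(X.sample_ids)
    X = np.asarray(X, dtype=float)
    return X, None, None


def train_ovr_logistic(
    X: TernaryMatrix | np.ndarray,
    y: Sequence[str],
    l2_strength: float = 1.0,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    normalize_output: bool = True,
) -> OvrLogisticModel:
    """Fit one L2-penalized binary logistic regression per city.

    ``l2_strength`` is the weight of the 0.5 * ||w||^2 penalty (the
    inverse of scikit-learn's C).  The fit is a deterministic convex
    optimization to gradient tolerance ``tol``; ``seed`` only labels the
    run, since L-BFGS from a fixed start is already deterministic.
    """
    matrix, feature_names, _ = _as_matrix(X)
    y = np.asarray(y)
    if matrix.shape[0] != y.shape[0]:
        raise ValueError("X and y are not aligned")
    cities = sorted(set(y))
    if len(cities) < 2:
        raise ValueError("need >= 2 cities to train a classifier")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(matrix.shape[1])]

    W = np.zeros((len(cities), matrix.shape[1]))
    theta = np.zeros(len(cities))
    for i, city in enumerate(cities):
        clf = LogisticRegression(
            C=1.0 / l2_strength,  # L2 penalty (the solver default)
            solver="lbfgs",
            tol=tol,
            max_iter=max_iter,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("always", category=ConvergenceWarning)
            clf.fit(matrix, (y == city).astype(int))
        W[i] = clf.coef_[0]
        theta[i] = clf.intercept_[0]

    return OvrLogisticModel(
        city_list=cities,
        feature_names=feature_names,
        W=W,
        theta=theta,
        l2_strength=l2_strength,
        normalize_output=normalize_output,
    )


def predict_city_probabilities(
    model: OvrLogisticModel, X: TernaryMatrix | np.ndarray
) -> pd.DataFrame:
    """Per-city probabilities for each sample (rows sum to 1 if normalized).

    A :class:`TernaryMatrix` input must carry exactly the model's
    features; its columns are re-ordered to the model's feature order.
    """
    if isinstance(X, TernaryMatrix):
        if set(X.taxa) != set(model.feature_names):
            raise ValueError("feature sets of input and model differ")
        X = X.subset_taxa(model.feature_names)
        matrix, _, sample_ids = _as_matrix(X)
    else:
        matrix, _, sample_ids = _as_matrix(X)
        if matrix.shape[1] != len(model.feature_names):
            raise ValueError("feature count does not match model")
    scores = model.sigmoid_scores(matrix)
    if model.normalize_output:
        scores = scores / scores.sum(axis=1, keepdims=True)
    index = sample_ids if sample_ids is not None else range(matrix.shape[0])
    return pd.DataFrame(scores, index=index, columns=model.city_list)


def evaluate(
    predictions: pd.DataFrame, truth: Sequence[str]
) -> tuple[float, pd.DataFrame, list]:
    """Accuracy and confusion matrix of argmax city assignments.

    Ties on the maximum probability go to the lexicographically first
    city; tied samples are returned for inspection.  Confusion-matrix
    rows are the true cities, columns the predicted cities.
    """
    truth = np.asarray(truth)
    if len(truth) != len(predictions):
        raise ValueError("predictions and truth are not aligned")
    cities = list(predictions.columns)
    unknown = sorted(set(truth) - set(cities))
    if unknown:
        raise ValueError(f"truth contains cities unknown to the model: {unknown}")

    ordered = predictions[sorted(cities)]  # lexicographic tie-break via first argmax
    scores = ordered.to_numpy()
    pred_idx = scores.argmax(axis=1)
    predicted = np.asarray(sorted(cities))[pred_idx]
    n_max = (scores == scores.max(axis=1, keepdims=True)).sum(axis=1)
    ties = [predictions.index[i] for i in np.nonzero(n_max > 1)[0]]

    confusion = pd.crosstab(
        pd.Series(truth, name="truth"),
        pd.Series(predicted, name="predicted"),
    ).reindex(index=sorted(cities), columns=sorted(cities), fill_value=0)
    accuracy = float(np.diag(confusion.to_numpy()).sum() / len(truth))
    return accuracy, confusion, ties


def save_model(model: OvrLogisticModel, path: str | Path) -> None:
    payload = {
        "city_list": model.city_list,
        "feature_names": model.feature_names,
        "W": model.W.tolist(),
        "theta": model.theta.tolist(),
        "l2_strength": model.l2_strength,
        "normalize_output": model.normalize_output,
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, sort_keys=True, indent=1)
        handle.write("\n")


def load_model(path: str | Path) -> OvrLogisticModel:
    with open(path) as handle:
        payload = json.load(handle)
    return OvrLogisticModel(
        city_list=payload["city_list"],
        feature_names=payload["feature_names"],
        W=np.array(payload["W"]),
        theta=np.array(payload["theta"]),
        l2_strength=payload["l2_strength"],
        normalize_output=payload["normalize_output"],
    )
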