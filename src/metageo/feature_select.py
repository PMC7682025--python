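"""Recursive feature elimination and shuffle-split evaluation.

Feature selection repeatedly fits the one-vs-rest logistic model,
scores each feature by the maximum absolute per-city coefficient, and
drops the ``step`` (default 5) lowest-scoring features per round until
the target subset size remains (default 50 in the full pipeline, chosen
to limit overfitting in the large-p small-n regime typical of
abundance profiles).  Evaluation uses repeated stratified 70/30
shuffle-splits, with elimination re-run on each split's training
portion only so the validation rows never inform the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .classify import evaluate, predict_city_probabilities, train_ovr_logistic
from .discretize import TernaryMatrix

__all__ = [
    "FeatureRanking",
    "SplitScheme",
    "rfe_rank",
    "shuffle_split_accuracy",
    "accuracy_vs_k_curve",
]


@dataclass
class FeatureRanking:
    """Outcome of recursive feature elimination.

    ``ranking`` orders taxa from most to least important: the
    ``support_k`` survivors first (in their original column order),
    then eliminated taxa in reverse order of elimination.
    ``round_eliminated`` maps each taxon to the round it was dropped
    (0 = survivor).
    """

    ranking: list[str]
    support_k: int
    round_eliminated: dict[str, int]

    @property
    def selected(self) -> list[str]:
        return self.ranking[: self.support_k]


@dataclass
class SplitScheme:
    """Repeated stratified shuffle-split configuration."""

    n_splits: int = 100
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def _importance(W: np.ndarray) -> np.ndarray:
    """Per-feature importance: max over cities of |coefficient|."""
    return np.abs(W).max(axis=0)


def rfe_rank(
    X: TernaryMatrix,
    y,
    step: int = 5,
    target_k: int = 50,
    l2_strength: float = 1.0,
    seed: int = 0,
) -> FeatureRanking:
    """Rank features by recursive elimination with the given step size.

    Each round fits the one-vs-rest model on the surviving features and
    removes the ``step`` lowest-importance ones (fewer on the final
    round so that exactly ``target_k`` survive).  Importance ties break
    by taxon lexicographic order for determinism.
    """
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    n_features = len(X.taxa)
    if target_k > n_features:
        raise ValueError(f"target_k={target_k} exceeds feature count {n_features}")

    y = np.asarray(y)
    surviving = list(range(n_features))
    round_eliminated: dict[str, int] = {t: 0 for t in X.taxa}
    eliminated_stack: list[str] = []  # later rounds appended last
    matrix = X.values.astype(float)
    taxa = np.asarray(X.taxa)

    round_no = 0
    while len(surviving) > target_k:
        round_no += 1
        model = train_ovr_logistic(
            matrix[:, surviving], y, l2_strength=l2_strength, seed=seed
        )
        if not np.all(np.isfinite(model.W)):
            raise FloatingPointError("non-finite coefficients during elimination")
        scores = _importance(model.W)
        n_drop = min(step, len(surviving) - target_k)
        # sort by (importance, taxon name): lowest importance dropped first,
        # ties resolved by taxon name so elimination is deterministic
        order = sorted(
            range(len(surviving)),
            key=lambda j: (scores[j], taxa[surviving[j]]),
        )
        drop = sorted(order[:n_drop], key=lambda j: taxa[surviving[j]])
        for j in drop:
            round_eliminated[str(taxa[surviving[j]])] = round_no
        eliminated_stack.extend(str(taxa[surviving[j]]) for j in drop)
        keep_mask = np.ones(len(surviving), dtype=bool)
        keep_mask[drop] = False
        surviving = [s for s, k in zip(surviving, keep_mask) if k]

    ranking = [str(taxa[s]) for s in surviving] + eliminated_stack[::-1]
    return FeatureRanking(ranking=ranking, support_k=target_k,
                          round_eliminated=round_eliminated)


def _split_indices(y: np.ndarray, scheme: SplitScheme):
    classes, counts = np.unique(y, return_counts=True)
    if scheme.stratified and counts.min() < 2:
        bad = classes[counts.argmin()]
        raise ValueError(
            f"city {bad!r} has a single sample; stratified splitting impossible"
        )
    n = len(y)
    n_train = int(np.floor(scheme.train_fraction * n))
    splitter = StratifiedShuffleSplit(
        n_splits=scheme.n_splits,
        train_size=n_train,
        test_size=n - n_train,
        random_state=scheme.seed,
    )
    return splitter.split(np.zeros((n, 1)), y)


def shuffle_split_accuracy(
    X: TernaryMatrix,
    y,
    scheme: SplitScheme,
    k_features: int = 50,
    step: int = 5,
    l2_strength: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Mean held-out accuracy over stratified 70/30 shuffle-splits.

    For each split, recursive elimination down to ``k_features`` and the
    classifier fit use the training portion only; accuracy is measured
    on the held-out 30%.  Fully determined by ``scheme.seed``.
    """
    y = np.asarray(y)
    accuracies = []
    for train_idx, test_idx in _split_indices(y, scheme):
        X_train = TernaryMatrix(
            [X.sample_ids[i] for i in train_idx], list(X.taxa), X.values[train_idx]
        )
        k = min(k_features, len(X.taxa))
        ranking = rfe_rank(X_train, y[train_idx], step=step, target_k=k,
                           l2_strength=l2_strength, seed=scheme.seed)
        X_train_sel = X_train.subset_taxa(ranking.selected)
        model = train_ovr_logistic(X_train_sel, y[train_idx],
                                   l2_strength=l2_strength, seed=scheme.seed)
        X_test = TernaryMatrix(
            [X.sample_ids[i] for i in test_idx], list(X.taxa), X.values[test_idx]
        ).subset_taxa(ranking.selected)
        preds = predict_city_probabilities(model, X_test)
        acc, _, _ = evaluate(preds, y[test_idx])
        accuracies.append(acc)
    accuracies = np.asarray(accuracies)
    return float(accuracies.mean()), accuracies


def accuracy_vs_k_curve(
    X: TernaryMatrix,
    y,
    scheme: SplitScheme,
    k_grid: list[int],
    step: int = 5,
    l2_strength: float = 1.0,
) -> list[tuple[int, float, float]]:
    """(k, mean accuracy, sd) for each subset size in ascending ``k_grid``."""
    if sorted(k_grid) != list(k_grid):
        raise ValueError("k_grid must be sorted ascending")
    curve = []
    for k in k_grid:
        mean, accs = shuffle_split_accuracy(X, y, scheme, k_features=k,
                                            step=step, l2_strength=l2_strength)
        curve.append((k, mean, float(accs.std())))
    return curve
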