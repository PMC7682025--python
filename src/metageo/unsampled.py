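"""Leave-one-city-out protocol for unsampled cities, with permutation null.

For each held-out city, every model artifact — binning thresholds,
feature selection, the one-vs-rest classifier, the PCA embedding, city
centroids, and the geographic-to-biological affine registration — is
rebuilt from the remaining cities' samples only, so no information
about the held-out city leaks into training.  The held-out city is
placed on the biological map by applying the affine transform to its
geographic coordinates; each of its samples' predicted probabilities
on the remaining cities are then kriged at that position to yield the
interpolated probability that the sample originates there.

Significance is assessed with a permutation null: training-sample city
labels are shuffled, the classifier, centroids, affine fit and kriging
are rerun (feature selection is frozen by default to bound cost — the
flag is recorded), and the observed interpolated probability is
compared with the null distribution.  The add-one p-value convention
(1 + #{null >= observed}) / (1 + N) keeps p-values strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biocoords import (AffineTransform, Pca2dEmbedding, apply_affine,
                        city_centroids, fit_affine, fit_pca_2d)
from .classify import OvrLogisticModel, predict_city_probabilities, train_ovr_logistic
from .config import RunConfig, stage_seed
from .discretize import (BinningThresholds, TernaryMatrix, apply_ternary_binning,
                         fit_binning_thresholds)
from .feature_select import rfe_rank
from .kriging import (VariogramModel, empirical_semivariogram, fit_variogram,
                      krige_probability)
from .profile_io import AbundanceTable, SampleMetadata

__all__ = ["LocoResult", "PermutationNull", "leave_one_city_out", "permutation_test"]


@dataclass
class LocoResult:
    """One held-out city's interpolation outcome plus frozen training context."""

    held_out_city: str
    sample_ids: list[str]
    anchor_probabilities: pd.DataFrame  # samples x remaining cities
    p_hat: np.ndarray  # interpolated probability at the held-out position
    clamped: np.ndarray  # per-sample clamp flags
    target_bio: np.ndarray  # (2,) affine-placed position of the held-out city
    anchor_cities: list[str]
    anchor_bio: np.ndarray  # (n_anchors, 2) centroid positions
    affine: AffineTransform
    # frozen context reused by the permutation test
    thresholds: BinningThresholds = field(repr=False, default=None)
    selected_taxa: list[str] = field(repr=False, default=None)
    embedding: Pca2dEmbedding = field(repr=False, default=None)
    train_sample_ids: list[str] = field(repr=False, default=None)
    train_labels: np.ndarray = field(repr=False, default=None)
    train_ternary: TernaryMatrix = field(repr=False, default=None)
    test_ternary: TernaryMatrix = field(repr=False, default=None)
    anchor_geo: np.ndarray = field(repr=False, default=None)
    model: OvrLogisticModel = field(repr=False, default=None)


@dataclass
class PermutationNull:
    """Per-sample permutation null of the interpolated probability."""

    held_out_city: str
    sample_ids: list[str]
    observed: np.ndarray  # (n_samples,)
    null: np.ndarray  # (n_samples, n_permutations)
    p_values: np.ndarray  # (n_samples,)
    n_permutations: int
    seed: int
    feature_selection_frozen: bool = True

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "observed_p_hat": self.observed,
            "null_median": np.median(self.null, axis=1),
            "p_value": self.p_values,
        })


def _krige_sample(anchor_bio, values, target, family):
    empirical = empirical_semivariogram(anchor_bio, values)
    model = fit_variogram(empirical, family=family)
    if model.degenerate:
        # flat semivariogram (near-constant anchor values): the parametric
        # system is singular, but predictions are scale-invariant, so a
        # unit-slope linear model gives the well-posed equivalent answer
        model = VariogramModel("linear", nugget=0.0, sill=1.0, range_=1.0)
    try:
        return krige_probability(anchor_bio, values, target, model)
    except np.linalg.LinAlgError:
        # gaussian covariance structures are famously ill-conditioned for
        # some anchor layouts; the linear family is the documented fallback
        model = fit_variogram(empirical, family="linear")
        if model.degenerate:
            model = VariogramModel("linear", nugget=0.0, sill=1.0, range_=1.0)
        return krige_probability(anchor_bio, values, target, model)


def _interpolate_all(anchor_bio, prob_frame, anchor_cities, target, family):
    values_matrix = prob_frame[anchor_cities].to_numpy()
    p_hat = np.empty(values_matrix.shape[0])
    clamped = np.empty(values_matrix.shape[0], dtype=bool)
    for i, values in enumerate(values_matrix):
        p_hat[i], clamped[i] = _krige_sample(anchor_bio, values, target, family)
    return p_hat, clamped


def leave_one_city_out(
    table: AbundanceTable,
    metadata: SampleMetadata,
    city_subset: list[str] | None = None,
    config: RunConfig | None = None,
) -> list[LocoResult]:
    """Run the full held-out-city protocol for every city in the subset."""
    config = config or RunConfig()
    cities_all = metadata.city_of(table.sample_ids)
    subset = sorted(set(cities_all)) if city_subset is None else sorted(city_subset)
    missing = [c for c in subset if c not in set(cities_all)]
    if missing:
        raise ValueError(f"cities without samples: {missing}")
    if len(subset) < 4:
        raise ValueError("need >= 4 cities (>= 3 affine anchors after holdout)")
    city_geo = metadata.city_coordinates()

    in_subset = np.isin(cities_all, subset)
    results = []
    for held_out in subset:
        train_mask = in_subset & (cities_all != held_out)
        test_mask = cities_all == held_out
        train_ids = [s for s, m in zip(table.sample_ids, train_mask) if m]
        test_ids = [s for s, m in zip(table.sample_ids, test_mask) if m]
        train_table = AbundanceTable(train_ids, list(table.taxa),
                                     table.values[train_mask])
        test_table = AbundanceTable(test_ids, list(table.taxa),
                                    table.values[test_mask])
        y_train = cities_all[train_mask]
        anchor_cities = sorted(set(y_train))

        thresholds = fit_binning_thresholds(train_table, axis=config.binning_axis)
        X_train = apply_ternary_binning(train_table, thresholds)
        k = min(config.target_k, len(table.taxa))
        ranking = rfe_rank(X_train, y_train, step=config.rfe_step, target_k=k,
                           l2_strength=config.l2_strength,
                           seed=stage_seed(config.seed, f"rfe:{held_out}"))
        selected = ranking.selected
        X_train_sel = X_train.subset_taxa(selected)
        model = train_ovr_logistic(X_train_sel, y_train,
                                   l2_strength=config.l2_strength,
                                   seed=stage_seed(config.seed, f"fit:{held_out}"),
                                   normalize_output=config.normalize_output)

        if config.pca_features == "raw":
            embed_train = train_table.values
        else:
            embed_train = X_train_sel.values.astype(float)
        embedding = fit_pca_2d(embed_train, sample_ids=train_ids)
        centroids = city_centroids(embedding, y_train)
        _, anchor_bio = centroids.as_arrays(anchor_cities)
        anchor_geo = city_geo.loc[anchor_cities].to_numpy()
        affine, _ = fit_affine(anchor_geo, anchor_bio)
        target_bio = apply_affine(affine, city_geo.loc[held_out].to_numpy())

        X_test_full = apply_ternary_binning(test_table, thresholds)
        probs = predict_city_probabilities(model, X_test_full.subset_taxa(selected))
        p_hat, clamped = _interpolate_all(anchor_bio, probs, anchor_cities,
                                          target_bio, config.variogram_family)

        results.append(LocoResult(
            held_out_city=held_out,
            sample_ids=test_ids,
            anchor_probabilities=probs,
            p_hat=p_hat,
            clamped=clamped,
            target_bio=np.asarray(target_bio),
            anchor_cities=anchor_cities,
            anchor_bio=anchor_bio,
            affine=affine,
            thresholds=thresholds,
            selected_taxa=selected,
            embedding=embedding,
            train_sample_ids=train_ids,
            train_labels=np.asarray(y_train),
            train_ternary=X_train,
            test_ternary=X_test_full,
            anchor_geo=anchor_geo,
            model=model,
        ))
    return results


def permutation_test(
    result: LocoResult,
    metadata: SampleMetadata,
    n_permutations: int = 1000,
    seed: int = 0,
    config: RunConfig | None = None,
) -> PermutationNull:
    """Permutation null for one held-out city's interpolated probabilities.

    Each permutation shuffles the training-sample city labels uniformly
    at random and reruns classifier training, centroid computation, the
    affine fit and kriging.  Feature selection (and the unsupervised
    thresholds and PCA embedding, which do not depend on labels) is
    frozen by default; set ``config.freeze_feature_selection = False``
    to rerun elimination per permutation.
    """
    config = config or RunConfig()
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(
        stage_seed(seed, f"permutation:{result.held_out_city}"))
    city_geo = metadata.city_coordinates()
    held_geo = city_geo.loc[result.held_out_city].to_numpy()
    anchor_cities = result.anchor_cities
    anchor_geo = result.anchor_geo

    n_test = len(result.sample_ids)
    null = np.empty((n_test, n_permutations))
    labels = result.train_labels.copy()
    for p in range(n_permutations):
        permuted = rng.permutation(labels)
        if config.freeze_feature_selection:
            selected = result.selected_taxa
        else:
            ranking = rfe_rank(result.train_ternary, permuted,
                               step=config.rfe_step,
                               target_k=len(result.selected_taxa),
                               l2_strength=config.l2_strength,
                               seed=stage_seed(seed, f"perm-rfe:{p}"))
            selected = ranking.selected
        X_train_sel = result.train_ternary.subset_taxa(selected)
        model = train_ovr_logistic(X_train_sel, permuted,
                                   l2_strength=config.l2_strength,
                                   seed=stage_seed(seed, f"perm-fit:{p}"),
                                   normalize_output=config.normalize_output)
        # PCA is unsupervised, so under frozen features the embedding is
        # unchanged by a label permutation; with re-selected features the
        # embedding's feature space changes and must be refit.
        if config.freeze_feature_selection or config.pca_features == "raw":
            embedding = result.embedding
        else:
            embedding = fit_pca_2d(X_train_sel.values.astype(float))
        centroids = city_centroids(embedding, permuted)
        _, anchor_bio = centroids.as_arrays(anchor_cities)
        affine, _ = fit_affine(anchor_geo, anchor_bio)
        target_bio = apply_affine(affine, held_geo)
        probs = predict_city_probabilities(
            model, result.test_ternary.subset_taxa(selected))
        null[:, p], _ = _interpolate_all(anchor_bio, probs, anchor_cities,
                                         target_bio, config.variogram_family)

    observed = result.p_hat
    p_values = (1 + (null >= observed[:, None]).sum(axis=1)) / (1 + n_permutations)
    return PermutationNull(
        held_out_city=result.held_out_city,
        sample_ids=list(result.sample_ids),
        observed=observed,
        null=null,
        p_values=p_values,
        n_permutations=n_permutations,
        seed=seed,
        feature_selection_frozen=config.freeze_feature_selection,
    )
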