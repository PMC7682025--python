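"""Biological coordinate system and geographic-to-biological registration.

Geographic proximity does not always track biological similarity of
urban microbiomes, so interpolation is carried out on a "biological"
map instead: a 2-D PCA embedding of the training profiles in which each
city sits at the centroid of its samples' scores.  Geographic (lon,
lat) positions are registered to this map with a six-parameter affine
transform fit by least squares over the sampled cities, using the
row-vector convention

    [x  y  1] @ [[m11, m12], [m21, m22], [t_x, t_y]] = [x', y']

so an unsampled city, known only by its geographic position, can be
placed on the biological map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Pca2dEmbedding",
    "CityCentroids",
    "AffineTransform",
    "fit_pca_2d",
    "city_centroids",
    "fit_affine",
    "apply_affine",
    "equirectangular",
]


@dataclass
class Pca2dEmbedding:
    """Top-2 principal components of the training feature matrix."""

    mean: np.ndarray  # (n_features,) column means used for centering
    loadings: np.ndarray  # (2, n_features), orthonormal rows
    scores: np.ndarray  # (n_samples, 2)
    sample_ids: list[str] | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) @ self.loadings.T


@dataclass
class CityCentroids:
    """Mean 2-D score per city, with the per-city sample count."""

    coordinates: dict[str, tuple[float, float]]
    counts: dict[str, int]

    def as_arrays(self, cities: list[str] | None = None) -> tuple[list[str], np.ndarray]:
        cities = sorted(self.coordinates) if cities is None else list(cities)
        return cities, np.array([self.coordinates[c] for c in cities])


@dataclass
class AffineTransform:
    """Six-parameter planar affine map (row-vector convention)."""

    m11: float
    m12: float
    m21: float
    m22: float
    t_x: float
    t_y: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_matrix())):
            raise ValueError("non-finite affine parameters")

    def as_matrix(self) -> np.ndarray:
        """3x2 matrix so that [x y 1] @ M = [x' y']."""
        return np.array(
            [[self.m11, self.m12], [self.m21, self.m22], [self.t_x, self.t_y]]
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {k: getattr(self, k) for k in
                 ("m11", "m12", "m21", "m22", "t_x", "t_y")},
                handle, sort_keys=True, indent=1,
            )
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        with open(path) as handle:
            return cls(**json.load(handle))


def fit_pca_2d(X: np.ndarray, sample_ids: list[str] | None = None) -> Pca2dEmbedding:
    """Mean-center and project onto the top-2 right singular vectors.

    Sign convention: within each loading vector the largest-magnitude
    entry is made positive, so the embedding is deterministic across
    platforms.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("PCA needs >= 3 samples")
    mean = X.mean(axis=0)
    centered = X - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(s) < 2 or s[1] <= max(X.shape) * np.finfo(float).eps * s[0]:
        raise ValueError("data has rank < 2; a 2-D embedding is degenerate")
    loadings = vt[:2].copy()
    for i in range(2):
        j = np.abs(loadings[i]).argmax()
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = centered @ loadings.T
    return Pca2dEmbedding(mean=mean, loadings=loadings, scores=scores,
                          sample_ids=sample_ids)


def city_centroids(embedding: Pca2dEmbedding, cities) -> CityCentroids:
    """Arithmetic mean of each city's sample scores (the city's position)."""
    cities = np.asarray(cities)
    if len(cities) != embedding.scores.shape[0]:
        raise ValueError("city labels not aligned with embedding scores")
    coordinates: dict[str, tuple[float, float]] = {}
    counts: dict[str, int] = {}
    for city in np.unique(cities):
        mask = cities == city
        if not mask.any():  # pragma: no cover - unique() precludes this
            warnings.warn(f"city {city!r} has no samples; excluded")
            continue
        mean = embedding.scores[mask].mean(axis=0)
        coordinates[str(city)] = (float(mean[0]), float(mean[1]))
        counts[str(city)] = int(mask.sum())
    return CityCentroids(coordinates=coordinates, counts=counts)


def fit_affine(geo_points: np.ndarray, bio_points: np.ndarray) -> tuple[AffineTransform, np.ndarray]:
    """Least-squares fit of the geo -> bio affine transform.

    Solves ``[x y 1] @ M = [x' y']`` for the six parameters over >= 3
    non-collinear anchor pairs via the normal equations (numpy lstsq).
    Returns the transform and the (n, 2) residual matrix.
    """
    geo = np.atleast_2d(np.asarray(geo_points, dtype=float))
    bio = np.atleast_2d(np.asarray(bio_points, dtype=float))
    if geo.shape != bio.shape or geo.shape[1] != 2:
        raise ValueError("geo and bio must both be (n, 2)")
    n = geo.shape[0]
    if n < 3:
        raise ValueError("affine fit needs >= 3 anchor pairs")
    design = np.column_stack([geo, np.ones(n)])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max())) < 3:
        raise ValueError("anchor geo points are collinear; affine fit is rank-deficient")
    params, _, _, _ = np.linalg.lstsq(design, bio, rcond=None)
    transform = AffineTransform(
        m11=float(params[0, 0]), m12=float(params[0, 1]),
        m21=float(params[1, 0]), m22=float(params[1, 1]),
        t_x=float(params[2, 0]), t_y=float(params[2, 1]),
    )
    residuals = bio - design @ params
    return transform, residuals


def apply_affine(transform: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Apply the row-vector affine map to (n, 2) points (or a single point)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = np.column_stack([pts, np.ones(pts.shape[0])]) @ transform.as_matrix()
    return out[0] if single else out


def equirectangular(lonlat: np.ndarray) -> np.ndarray:
    """Optional planar scaling lon * cos(mean lat) for high-latitude city sets."""
    lonlat = np.atleast_2d(np.asarray(lonlat, dtype=float))
    scale = np.cos(np.deg2rad(lonlat[:, 1].mean()))
    return np.column_stack([lonlat[:, 0] * scale, lonlat[:, 1]])
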