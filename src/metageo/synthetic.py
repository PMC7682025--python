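"""Synthetic multi-city microbiome datasets with planted spatial structure.

The generator emulates the structure of a multi-city urban-microbiome
survey: a modest number of cities with unbalanced per-city sample
counts (10-26 by default, as in typical subway-swab collections),
sparse percent-scale abundance profiles with many exact zeros, and a
per-city signature whose similarity decays with distance — not on the
geographic map directly, but on a latent 2-D "biological" map related
to geography by a planted affine transform.  That is exactly the
continuity assumption the interpolation pipeline relies on ("near
things are more related than distant things"), so every stage of the
pipeline can be exercised, and its assumptions broken on purpose, with
full ground truth in hand.

Mechanics: city geographic positions are drawn uniformly in a bounding
box (with a minimum-separation constraint); each city's biological
position is the planted affine image of its geographic position.  Each
informative taxon responds to the biological map through a Gaussian
bump — its log-mean abundance peaks at a random center and decays with
the configured length scale — while uninformative taxa are i.i.d.
noise.  Per-sample log-normal noise is added, values are exponentiated,
rows are normalized to percent, and the smallest fraction of each row
is zeroed to mimic profiler sparsity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biocoords import AffineTransform, apply_affine
from .profile_io import AbundanceTable, SampleMetadata

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate",
    "summarize",
    "strong_separation_config",
    "smooth_spatial_config",
]


@dataclass
class SimConfig:
    """Knobs of the synthetic-data generator.

    Defaults mirror the regime of a 16-city urban survey: unbalanced
    city sizes between 10 and 26 samples, thousands of clade-level
    features of which a small subset is geographically informative,
    and a Europe-sized geographic window.
    """

    n_cities: int = 16
    samples_per_city: list[int] | None = None  # None: draw in [10, 26]
    n_taxa: int = 5503
    n_informative_taxa: int = 50
    bbox: tuple[float, float, float, float] = (-10.0, 30.0, 35.0, 60.0)  # lon0, lon1, lat0, lat1
    affine: AffineTransform = field(
        default_factory=lambda: AffineTransform(1.4, 0.3, -0.2, 1.1, 2.0, -1.0)
    )
    length_scale: float = 0.35  # fraction of the bio-map diagonal
    noise_sd: float = 0.5  # sd of log-scale per-sample noise
    bump_amplitude: float = 3.0  # log-scale dynamic range of informative taxa
    sparsity: float = 0.3  # fraction of smallest entries zeroed per sample
    min_city_separation: float = 0.05  # fraction of the bbox diagonal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_taxa > self.n_taxa:
            raise ValueError("n_informative_taxa must be <= n_taxa")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if self.samples_per_city is not None:
            if len(self.samples_per_city) != self.n_cities:
                raise ValueError("samples_per_city length must equal n_cities")
            if min(self.samples_per_city) < 1:
                raise ValueError("samples_per_city entries must be >= 1")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    table: AbundanceTable
    metadata: SampleMetadata
    bio_coordinates: dict[str, tuple[float, float]]  # planted affine of geo
    informative_taxa: list[str]
    config: SimConfig

    def write(self, profiles_path: str | Path, metadata_path: str | Path,
              truth_path: str | Path | None = None) -> None:
        from .profile_io import write_wide_tsv

        write_wide_tsv(self.table, profiles_path)
        self.metadata.frame.to_csv(metadata_path, sep="\t", index=False)
        if truth_path is not None:
            with open(truth_path, "w") as handle:
                json.dump(
                    {
                        "bio_coordinates": self.bio_coordinates,
                        "informative_taxa": self.informative_taxa,
                    },
                    handle, sort_keys=True, indent=1,
                )
                handle.write("\n")


def strong_separation_config(
    n_cities: int = 8,
    samples_per_city: int = 20,
    n_taxa: int = 500,
    n_informative_taxa: int = 50,
    seed: int = 0,
) -> SimConfig:
    """Sharply separated city signatures (classification regime).

    A short spatial length scale maximizes between-city contrast on the
    informative taxa, the regime in which the sampled-city classifier
    is expected to recover the label reliably.
    """
    return SimConfig(
        n_cities=n_cities,
        samples_per_city=[samples_per_city] * n_cities,
        n_taxa=n_taxa,
        n_informative_taxa=n_informative_taxa,
        bump_amplitude=4.0,
        noise_sd=0.3,
        length_scale=0.2,
        seed=seed,
    )


def smooth_spatial_config(
    n_cities: int = 8,
    samples_per_city: int = 15,
    n_taxa: int = 500,
    n_informative_taxa: int = 50,
    seed: int = 0,
) -> SimConfig:
    """Smooth spatial signatures (interpolation regime).

    A longer length scale makes each taxon's response vary gently
    between neighboring cities, so the PCA map is close to an affine
    image of geography and held-out cities can be interpolated — the
    continuity assumption the unsampled-city protocol relies on.
    """
    return SimConfig(
        n_cities=n_cities,
        samples_per_city=[samples_per_city] * n_cities,
        n_taxa=n_taxa,
        n_informative_taxa=n_informative_taxa,
        bump_amplitude=4.0,
        noise_sd=0.3,
        length_scale=0.4,
        seed=seed,
    )


def _place_cities(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    lon0, lon1, lat0, lat1 = config.bbox
    diag = float(np.hypot(lon1 - lon0, lat1 - lat0))
    min_dist = config.min_city_separation * diag
    for _ in range(200):
        lon = rng.uniform(lon0, lon1, config.n_cities)
        lat = rng.uniform(lat0, lat1, config.n_cities)
        pts = np.column_stack([lon, lat])
        dists = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= min_dist:
            return pts
    raise RuntimeError(
        "could not place cities with the requested minimum separation"
    )


def generate(config: SimConfig) -> SyntheticDataset:
    """Generate a dataset from the configuration (byte-reproducible by seed)."""
    rng = np.random.default_rng(config.seed)
    geo = _place_cities(rng, config)
    cities = [f"city_{i:02d}" for i in range(config.n_cities)]
    bio = apply_affine(config.affine, geo)

    if config.samples_per_city is None:
        counts = rng.integers(10, 27, size=config.n_cities)
    else:
        counts = np.asarray(config.samples_per_city)

    taxa = [f"k__Synthetica|s__taxon_{j:05d}" for j in range(config.n_taxa)]
    informative = taxa[: config.n_informative_taxa]

    # Gaussian-bump response surfaces on the biological map
    bio_min, bio_max = bio.min(axis=0), bio.max(axis=0)
    bio_diag = max(float(np.linalg.norm(bio_max - bio_min)), 1.0)
    ell = config.length_scale * bio_diag
    centers = rng.uniform(bio_min, bio_max,
                          size=(config.n_informative_taxa, 2))
    base = 0.0  # log-scale baseline; only contrasts matter after normalization

    sample_ids, sample_city, rows = [], [], []
    for c, city in enumerate(cities):
        d2 = ((bio[c] - centers) ** 2).sum(axis=1)
        log_mean_inf = base + config.bump_amplitude * np.exp(-d2 / (2 * ell**2))
        for k in range(counts[c]):
            sid = f"{city}_s{k:03d}"
            log_val = np.full(config.n_taxa, base)
            log_val[: config.n_informative_taxa] = log_mean_inf
            log_val = log_val + config.noise_sd * rng.standard_normal(config.n_taxa)
            val = np.exp(log_val)
            val = 100.0 * val / val.sum()
            if config.sparsity > 0:
                n_zero = int(np.floor(config.sparsity * config.n_taxa))
                if n_zero:
                    order = np.argsort(val, kind="stable")
                    val[order[:n_zero]] = 0.0
                    val = 100.0 * val / val.sum()
            sample_ids.append(sid)
            sample_city.append(city)
            rows.append(val)

    table = AbundanceTable(sample_ids=sample_ids, taxa=taxa,
                           values=np.asarray(rows))
    meta = SampleMetadata(frame=pd.DataFrame({
        "sample_id": sample_ids,
        "city": sample_city,
        "lon": [geo[cities.index(c), 0] for c in sample_city],
        "lat": [geo[cities.index(c), 1] for c in sample_city],
    }))
    bio_coords = {c: (float(bio[i, 0]), float(bio[i, 1]))
                  for i, c in enumerate(cities)}
    return SyntheticDataset(table=table, metadata=meta,
                            bio_coordinates=bio_coords,
                            informative_taxa=informative, config=config)


def summarize(dataset: SyntheticDataset, cap: float = 1e6) -> pd.DataFrame:
    """Per-city-pair separation on the informative taxa.

    The statistic is the mean between-city sample distance divided by
    the mean within-city sample distance (pooled over the pair), so it
    is ~1 when labels carry no signal and grows without bound (capped)
    as noise vanishes.
    """
    taxa_idx = [dataset.table.taxa.index(t) for t in dataset.informative_taxa]
    X = dataset.table.values[:, taxa_idx]
    cities = dataset.metadata.city_of(dataset.table.sample_ids)

    def mean_pairwise(A: np.ndarray, B: np.ndarray | None = None) -> float:
        if B is None:
            n = A.shape[0]
            if n < 2:
                return np.nan
            d = np.linalg.norm(A[:, None] - A[None, :], axis=-1)
            return float(d[np.triu_indices(n, 1)].mean())
        return float(np.linalg.norm(A[:, None] - B[None, :], axis=-1).mean())

    unique = sorted(set(cities))
    records = []
    for i, a in enumerate(unique):
        Xa = X[cities == a]
        for b in unique[i + 1:]:
            Xb = X[cities == b]
            between = mean_pairwise(Xa, Xb)
            within = np.nanmean([mean_pairwise(Xa), mean_pairwise(Xb)])
            ratio = cap if within == 0 or np.isnan(within) else min(between / within, cap)
            records.append({"city_a": a, "city_b": b, "separation": ratio})
    return pd.DataFrame.from_records(records)
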