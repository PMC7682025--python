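"""Reading, merging and aligning taxonomic abundance tables.

Abundance tables are the output of metagenomic profilers (MetaPhlAn-style
or Kraken mpa-style reports): one row per clade, identified by a
rank-prefixed lineage string such as
``k__Bacteria|p__Firmicutes|...|s__Streptococcus_salivarius``, with the
relative abundance of that clade in each sample expressed in percent.
All clade levels (kingdom through species) are retained; a clade absent
from a sample is an exact zero, so that every sample ends up with the
same feature set after merging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "AbundanceTable",
    "SampleMetadata",
    "ParseError",
    "rank_of",
    "read_abundance_report",
    "read_metadata",
    "merge_tables",
    "subset_by_rank",
    "write_wide_tsv",
]

#: Taxonomic ranks orderable from shallowest to deepest, keyed by the
#: single-letter prefix used in clade strings (``k__``, ``p__``, ...).
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "k": "kingdom",
    "d": "kingdom",  # Kraken writes d__ for domain; treated as kingdom level
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

_RANK_DEPTH = {rank: i for i, rank in enumerate(RANKS)}


class ParseError(ValueError):
    """Raised when an abundance report cannot be parsed."""


def rank_of(clade_string: str) -> str:
    """Return the taxonomic rank of a clade string.

    The rank is the deepest rank prefix present in the pipe-separated
    lineage.  Unknown prefixes are rejected rather than guessed.
    """
    best: str | None = None
    for part in clade_string.split("|"):
        if len(part) < 3 or part[1:3] != "__":
            raise ParseError(f"clade segment without rank prefix: {part!r}")
        prefix = part[0].lower()
        if prefix not in _PREFIX_TO_RANK:
            raise ParseError(f"unknown rank prefix {part[0]!r} in {clade_string!r}")
        rank = _PREFIX_TO_RANK[prefix]
        if best is None or _RANK_DEPTH[rank] > _RANK_DEPTH[best]:
            best = rank
    if best is None:
        raise ParseError(f"empty clade string: {clade_string!r}")
    return best


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of relative abundances in percent.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers (row order).
    taxa : list of str
        Unique rank-prefixed clade strings (column order).
    values : ndarray of shape (n_samples, n_taxa)
        Relative abundances in percent; finite and >= 0, with absent
        (sample, taxon) combinations stored as exact 0.
    """

    sample_ids: list[str]
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_s, n_t = len(self.sample_ids), len(self.taxa)
        if self.values.shape != (n_s, n_t):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n_s} samples x {n_t} taxa"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")
        if len(set(self.taxa)) != n_t:
            raise ValueError("duplicate taxa")
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or np.any(self.values < 0)
        ):
            raise ValueError("abundance values must be finite and >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxa)

    def ranks(self) -> list[str]:
        """Rank of each taxon column."""
        return [rank_of(t) for t in self.taxa]


@dataclass
class SampleMetadata:
    """Per-sample city label and geographic coordinates."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "city", "lon", "lat"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        lon = self.frame["lon"].to_numpy(dtype=float)
        lat = self.frame["lat"].to_numpy(dtype=float)
        if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
            raise ValueError("lon/lat outside valid degree ranges")
        self.frame = self.frame.set_index("sample_id", drop=False)

    def city_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples without metadata: {missing[:5]}")
        return self.frame.loc[list(sample_ids), "city"].to_numpy()

    def city_coordinates(self) -> pd.DataFrame:
        """One (lon, lat) row per city; coordinates must agree within a city."""
        coords = self.frame.groupby("city")[["lon", "lat"]].agg(["min", "max"])
        if not np.allclose(coords.xs("min", axis=1, level=1),
                           coords.xs("max", axis=1, level=1)):
            raise ValueError("inconsistent coordinates within a city")
        return self.frame.groupby("city")[["lon", "lat"]].first()


def _parse_percent(token: str, path: str, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: cannot parse abundance value {token!r}"
        ) from None
    if not np.isfinite(value) or value < 0:
        raise ParseError(f"{path}:{lineno}: abundance value {value} out of range")
    return value


def read_abundance_report(path: str | Path, dialect: str = "metaphlan") -> AbundanceTable:
    """Read a profiler report into an :class:`AbundanceTable`.

    Parameters
    ----------
    path : str
        TSV file to read.
    dialect : {"metaphlan", "kraken_mpa", "wide_tsv"}
        ``metaphlan`` and ``kraken_mpa`` share a layout: first column is
        the clade string (header ``#clade_name`` or ``clade_name``),
        remaining columns are per-sample percentages.  ``wide_tsv`` is
        the transposed layout used for round-trips: header row = taxa,
        first column = sample id.
    """
    path = Path(path)
    if dialect not in ("metaphlan", "kraken_mpa", "wide_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")

    header = lines[0].split("\t")
    if dialect == "wide_tsv":
        taxa = header[1:]
        sample_ids: list[str] = []
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, "
                                 f"got {len(fields)}")
            sample_ids.append(fields[0])
            rows.append([_parse_percent(tok, str(path), lineno) for tok in fields[1:]])
        values = np.asarray(rows, dtype=float).reshape(len(sample_ids), len(taxa))
    else:
        first = header[0].lstrip("#").strip()
        if first.lower() not in ("clade_name", "taxon", "taxonomy"):
            raise ParseError(f"{path}:1: unrecognized clade column header {header[0]!r}")
        sample_ids = header[1:]
        taxa = []
        seen: set[str] = set()
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, "
                                 f"got {len(fields)}")
            clade = fields[0]
            if clade in seen:
                raise ParseError(f"{path}:{lineno}: duplicate taxon {clade!r}")
            rank_of(clade)  # validates the prefixes
            seen.add(clade)
            taxa.append(clade)
            rows.append([_parse_percent(tok, str(path), lineno) for tok in fields[1:]])
        values = np.asarray(rows, dtype=float).T.reshape(len(sample_ids), len(taxa))

    return AbundanceTable(sample_ids=list(sample_ids), taxa=list(taxa), values=values)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample metadata TSV (columns sample_id, city, lon, lat)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "city": str})
    return SampleMetadata(frame=frame)


def merge_tables(tables: Sequence[AbundanceTable]) -> AbundanceTable:
    """Merge tables over the union of their taxa, zero-filling absences.

    Taxon order in the result is lexicographic on the clade string, so
    merging is associative and order-insensitive.  Sample ids must be
    disjoint across inputs.
    """
    if not tables:
        raise ValueError("merge_tables requires a non-empty list")
    all_samples: list[str] = []
    for t in tables:
        all_samples.extend(t.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        dupes = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValueError(f"overlapping sample ids across tables: {dupes[:5]}")

    taxa = sorted(set().union(*(t.taxa for t in tables)))
    col = {taxon: j for j, taxon in enumerate(taxa)}
    values = np.zeros((len(all_samples), len(taxa)))
    row = 0
    for t in tables:
        idx = [col[taxon] for taxon in t.taxa]
        values[row : row + t.n_samples, idx] = t.values
        row += t.n_samples
    return AbundanceTable(sample_ids=all_samples, taxa=taxa, values=values)


def subset_by_rank(table: AbundanceTable, ranks: Iterable[str]) -> AbundanceTable:
    """Keep only taxa whose rank is in ``ranks``; samples are unchanged."""
    ranks = set(ranks)
    if not ranks:
        raise ValueError("ranks must be non-empty")
    unknown = ranks - set(RANKS)
    if unknown:
        raise ValueError(f"unknown ranks: {sorted(unknown)}")
    keep = [j for j, t in enumerate(table.taxa) if rank_of(t) in ranks]
    if not keep:
        warnings.warn("rank subset removed every taxon", stacklevel=2)
    return AbundanceTable(
        sample_ids=list(table.sample_ids),
        taxa=[table.taxa[j] for j in keep],
        values=table.values[:, keep] if keep else np.zeros((table.n_samples, 0)),
    )


def write_wide_tsv(table: AbundanceTable, path: str | Path) -> None:
    """Write the wide TSV layout (rows = samples) with full float precision."""
    with open(path, "w") as handle:
        handle.write("\t".join(["sample_id", *table.taxa]) + "\n")
        for i, sid in enumerate(table.sample_ids):
            row = "\t".join(repr(float(v)) for v in table.values[i])
            handle.write(f"{sid}\t{row}\n" if table.n_taxa else f"{sid}\n")
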