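"""Ternary discretization of abundance profiles.

Relative abundances are binned to {-1, 0, 1} against the 25th and 75th
percentiles of the training data:

    f(x) = -1  if x < P25
            0  if P25 <= x < P75
            1  if x >= P75

so that only salient differences between samples survive as features,
suppressing trivially small variation in the profiles.  The percentiles
are learned per feature across training samples by default (test samples
are then binned against training-derived cut points, avoiding leakage);
a per-sample mode, where P25/P75 are taken across taxa within each
sample at application time, is available as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .profile_io import AbundanceTable

__all__ = [
    "BinningThresholds",
    "TernaryMatrix",
    "fit_binning_thresholds",
    "apply_ternary_binning",
    "write_thresholds",
    "read_thresholds",
]

QUANTILE_METHOD = "linear"  # linear interpolation between order statistics


@dataclass
class BinningThresholds:
    """P25/P75 cut points for ternary binning.

    In ``per_feature`` mode ``p25``/``p75`` hold one pair per taxon,
    computed across training samples.  In ``per_sample`` mode the cut
    points are recomputed across taxa within each sample when applied,
    so only the convention is stored and the arrays are empty.
    """

    taxa: list[str]
    p25: np.ndarray
    p75: np.ndarray
    axis: str = "per_feature"
    percentile_method: str = QUANTILE_METHOD

    def __post_init__(self) -> None:
        if self.axis not in ("per_feature", "per_sample"):
            raise ValueError(f"unknown axis {self.axis!r}")
        self.p25 = np.asarray(self.p25, dtype=float)
        self.p75 = np.asarray(self.p75, dtype=float)
        if self.axis == "per_feature":
            if not (len(self.taxa) == self.p25.size == self.p75.size):
                raise ValueError("threshold arrays must align with taxa")
            if np.any(self.p25 > self.p75):
                raise ValueError("p25 > p75 for some feature")


@dataclass
class TernaryMatrix:
    """Samples x taxa matrix with entries in {-1, 0, 1}."""

    sample_ids: list[str]
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sample_ids), len(self.taxa)):
            raise ValueError("shape mismatch")
        if self.values.size and not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("entries must be -1, 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_taxa(self, taxa: list[str]) -> "TernaryMatrix":
        col = {t: j for j, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in col]
        if missing:
            raise KeyError(f"taxa not present: {missing[:5]}")
        idx = [col[t] for t in taxa]
        return TernaryMatrix(list(self.sample_ids), list(taxa), self.values[:, idx])


def fit_binning_thresholds(train: AbundanceTable, axis: str = "per_feature") -> BinningThresholds:
    """Learn P25/P75 cut points from a training table.

    Quantiles use linear interpolation between order statistics (the
    convention is recorded on the result for reproducibility).
    """
    if axis not in ("per_feature", "per_sample"):
        raise ValueError(f"unknown axis {axis!r}")
    if train.n_samples == 0 or train.n_taxa == 0:
        raise ValueError("cannot fit thresholds on an empty table")
    if axis == "per_feature":
        if train.n_samples < 2:
            raise ValueError("per_feature thresholds need >= 2 training samples")
        p25 = np.percentile(train.values, 25, axis=0, method=QUANTILE_METHOD)
        p75 = np.percentile(train.values, 75, axis=0, method=QUANTILE_METHOD)
        return BinningThresholds(list(train.taxa), p25, p75, axis=axis)
    if train.n_taxa < 2:
        raise ValueError("per_sample thresholds need >= 2 taxa")
    return BinningThresholds(list(train.taxa), np.empty(0), np.empty(0), axis=axis)


def _ternary(values: np.ndarray, p25: np.ndarray, p75: np.ndarray) -> np.ndarray:
    out = np.zeros(values.shape, dtype=np.int8)
    out[values < p25] = -1
    out[values >= p75] = 1
    return out


def apply_ternary_binning(table: AbundanceTable, thresholds: BinningThresholds) -> TernaryMatrix:
    """Bin a table against learned thresholds.

    Boundary semantics are exact: x == P25 maps to 0 and x == P75 maps
    to 1, so a constant feature (P25 == P75) maps entirely to 1.
    """
    if thresholds.axis == "per_sample":
        p25 = np.percentile(table.values, 25, axis=1, keepdims=True,
                            method=thresholds.percentile_method)
        p75 = np.percentile(table.values, 75, axis=1, keepdims=True,
                            method=thresholds.percentile_method)
        values = _ternary(table.values, p25, p75)
        return TernaryMatrix(list(table.sample_ids), list(table.taxa), values)

    col = {t: j for j, t in enumerate(thresholds.taxa)}
    missing = [t for t in table.taxa if t not in col]
    if missing:
        raise KeyError(f"taxa without thresholds: {missing[:5]}")
    idx = [col[t] for t in table.taxa]
    values = _ternary(table.values, thresholds.p25[idx], thresholds.p75[idx])
    return TernaryMatrix(list(table.sample_ids), list(table.taxa), values)


def write_thresholds(thresholds: BinningThresholds, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# axis={thresholds.axis}\t"
                     f"method={thresholds.percentile_method}\n")
        handle.write("taxon\tp25\tp75\n")
        if thresholds.axis == "per_feature":
            for taxon, lo, hi in zip(thresholds.taxa, thresholds.p25, thresholds.p75):
                handle.write(f"{taxon}\t{float(lo)!r}\t{float(hi)!r}\n")


def read_thresholds(path: str | Path) -> BinningThresholds:
    with open(path) as handle:
        meta = dict(tok.split("=", 1) for tok in
                    handle.readline().lstrip("#").split())
        handle.readline()  # column header
        taxa, p25, p75 = [], [], []
        for line in handle:
            taxon, lo, hi = line.rstrip("\n").split("\t")
            taxa.append(taxon)
            p25.append(float(lo))
            p75.append(float(hi))
    return BinningThresholds(taxa, np.array(p25), np.array(p75),
                             axis=meta["axis"], percentile_method=meta["method"])
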