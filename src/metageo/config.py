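"""Run configuration shared by the pipelines and the command line.

A single global seed is fanned out to stage-specific substreams keyed
by the stage name, so adding or reordering a stage never perturbs
another stage's randomness.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_seed", "stage_rng"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


@dataclass
class RunConfig:
    """All pipeline knobs, with defaults matching the standard protocol:

    ternary binning against per-feature P25/P75 training percentiles,
    recursive elimination with step 5 down to 50 features, 100
    stratified 70/30 shuffle-splits for evaluation, an L2-regularized
    one-vs-rest logistic classifier, gaussian variogram for kriging,
    and a 1000-permutation null.
    """

    binning_axis: str = "per_feature"
    rfe_step: int = 5
    target_k: int = 50
    n_splits: int = 100
    train_fraction: float = 0.7
    l2_strength: float = 1.0
    normalize_output: bool = True
    variogram_family: str = "gaussian"
    pca_features: str = "raw"  # or "binned_selected"
    n_permutations: int = 1000
    freeze_feature_selection: bool = True
    city_subset: list[str] | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
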