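import warnings

import numpy as np
import pytest

from metageo import RunConfig, SimConfig, generate
from metageo.discretize import apply_ternary_binning, fit_binning_thresholds


@pytest.fixture(autouse=True)
def _quiet_variogram_warnings():
    # tiny anchor sets legitimately trigger the documented linear fallback
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*falling back to linear.*")
        warnings.filterwarnings("ignore", message=".*semivariogram bins.*")
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """5 cities x 8 samples, 80 taxa (15 informative), separable signal."""
    cfg = SimConfig(
        n_cities=5,
        samples_per_city=[8] * 5,
        n_taxa=80,
        n_informative_taxa=15,
        bump_amplitude=4.0,
        noise_sd=0.3,
        length_scale=0.25,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_ternary(small_dataset):
    thresholds = fit_binning_thresholds(small_dataset.table)
    X = apply_ternary_binning(small_dataset.table, thresholds)
    y = small_dataset.metadata.city_of(small_dataset.table.sample_ids)
    return X, np.asarray(y)
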