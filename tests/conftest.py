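import numpy as np
import pandas as pd
import pytest

from soilsqi.preprocess import SpectralSet
from soilsqi.synthetic import default_config, simulate_dataset


@pytest.fixture
def tiny_spectra():
    """Three samples x two replicates on a 5-band grid."""
    wl = np.array([400.0, 410.0, 420.0, 430.0, 440.0])
    rng = np.random.default_rng(7)
    values = rng.normal(size=(6, 5))
    return SpectralSet(
        wavelengths=wl,
        values=values,
        sample_ids=np.repeat(["a", "b", "c"], 2),
        rep_ids=np.tile([0, 1], 3),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset on a coarse grid, shared across tests."""
    cfg = default_config(n_samples=200, step_nm=25.0, seed=11)
    props, spectra = simulate_dataset(cfg)
    return cfg, props, spectra
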