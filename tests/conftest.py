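import numpy as np
import pytest

from bananachem import SpectraDataset, SyntheticConfig, generate_spectra_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_dataset():
    """A tiny deterministic reflectance dataset for transform tests."""
    rng = np.random.default_rng(99)
    X = 0.2 + 0.6 * rng.random((6, 12))
    wl = np.linspace(400, 1000, 12)
    return SpectraDataset(X=X, wavelengths=wl)


@pytest.fixture()
def scaled_config():
    """The scaled-down study conditions: 60 bands, 99 samples."""
    return SyntheticConfig(seed=0, n_bands=60, n_samples=99)


@pytest.fixture()
def scaled_data(scaled_config):
    return generate_spectra_dataset(scaled_config)
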