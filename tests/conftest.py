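import numpy as np
import pytest

from szpipe.features import build_feature_table
from szpipe.signal_io import bandpass_filter
from szpipe.synthdata import SynthConfig, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_interictal=60, n_ictal=30, seed=0)


@pytest.fixture(scope="session")
def small_segments(small_config):
    return [bandpass_filter(s) for s in gen_dataset(small_config)]


@pytest.fixture(scope="session")
def small_table(small_segments):
    return build_feature_table(small_segments)


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs in 24-D, labelled like feature tables."""
    r = np.random.default_rng(7)
    n = 200
    a = r.normal(loc=0.2, scale=0.05, size=(n, 24))
    b = r.normal(loc=0.8, scale=0.05, size=(n, 24))
    X = np.vstack([a, b])
    y = np.array(["interictal"] * n + ["ictal"] * n)
    return X, y
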