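import numpy as np
import pytest

from ducknet.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, easy synthetic dataset shared across training tests."""
    return generate_dataset(
        SynthConfig(n_samples=24, size=32, blob_radius_fraction=(0.1, 0.3), seed=7))


@pytest.fixture()
def checker_mask():
    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[::2, ::2] = 1
    return mask
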