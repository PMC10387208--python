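import numpy as np
import pytest

from sdrvessel.synthetic import SynthConfig, generate_sample


@pytest.fixture(scope="session")
def tiny_samples():
    """8 synthetic 64x64 fundus samples, fixed seeds, shared across tests."""
    cfg = SynthConfig()
    return [generate_sample(cfg, 100 + i, 200 + i, f"s{i}") for i in range(8)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
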