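import numpy as np
import pytest

from emphcn.model import ModelConfig
from emphcn.synthgen import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def toy_network():
    """Small synthetic network with a protein layer (30 drugs, 40 diseases)."""
    cfg = SynthConfig(m=30, n=40, p=50, s=3, rank=3, density=0.1, seed=7)
    network, truth = generate_dataset(cfg)
    return network, truth


@pytest.fixture(scope="session")
def micro_network():
    """Tiny network for gradient checks and fast forward passes."""
    cfg = SynthConfig(m=4, n=3, p=6, s=2, rank=2, density=0.3, seed=5)
    network, truth = generate_dataset(cfg)
    return network, truth


@pytest.fixture
def micro_model_config():
    return ModelConfig(k1=5, k2=4, knn_k=2, beta=0.0, gamma=0.0, seed=11, epochs=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
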