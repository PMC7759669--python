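import numpy as np
import pytest

from stsanet.model import ModelConfig, STSANet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """A small geometry that exercises every stage of the architecture."""
    return ModelConfig(
        n_channels=4,
        n_samples=64,
        att_maps=2,
        head_maps=4,
        temporal_kernel=7,
        pool_kernel=8,
        pool_stride=4,
        n_classes=3,
        dropout_p=0.0,
    )


@pytest.fixture
def tiny_model(tiny_config):
    m = STSANet(tiny_config)
    m.init_parameters(0)
    return m
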