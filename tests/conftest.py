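import numpy as np
import pytest

from lka3d.unet import NetworkConfig, Placement


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net_config():
    """Three-scale toy network with one attention module (fast to run)."""
    return NetworkConfig(
        in_channels=1, out_channels=3, base_width=4, n_scales=3,
        input_shape=(16, 16, 16), attention_placements=[Placement(1, 6, 2)],
    )
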