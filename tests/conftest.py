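import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net():
    """A small dense network with learnable delays, fixed seed."""
    from snndelays.network import NetworkConfig, SpikingDelayNet

    cfg = NetworkConfig(
        n_inputs=5, n_hidden=7, n_outputs=3, T=20, T_d=6,
        dropout_p=0.0, batch_norm=False, dale=False,
        learn_structure=False, learn_delays=True, sparsity_level=0.0,
    )
    return SpikingDelayNet(cfg, np.random.default_rng(3))
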