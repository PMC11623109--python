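import numpy as np
import pytest

import ultraseg as us


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest usable network: 32x32 input, narrow filter schedule."""
    return us.ModelConfig(input_height=32, input_width=32,
                          filter_schedule=(4, 8, 16, 24, 32), seed=0)


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    return us.build_network(tiny_config)


@pytest.fixture(scope="session")
def default_graph():
    return us.assemble_model(us.ModelConfig())


@pytest.fixture(scope="session")
def phantom_batch():
    """A dozen 64x64 lesion phantoms shared by the slower pipeline tests."""
    return us.surrogate_phantoms(12, 42)
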