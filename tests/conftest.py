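import numpy as np
import pytest

from dwpsim.experiments import SimConfig


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def base_config():
    return SimConfig()
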