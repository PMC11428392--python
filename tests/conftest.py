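import numpy as np
import pytest

from landloc.synthetic import SyntheticConfig, make_dataset
from landloc.topology import default_hand_topology


@pytest.fixture(scope="session")
def topology():
    return default_hand_topology()


@pytest.fixture(scope="session")
def small_dataset():
    """12 synthetic hands at 64x64, shared across tests."""
    return make_dataset(SyntheticConfig(n_images=12, frame=(64, 64), seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
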