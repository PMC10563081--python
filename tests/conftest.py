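import numpy as np
import pytest

from hnscnet.config import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20230904)


@pytest.fixture
def small_config():
    """A fast generator configuration for unit tests."""
    return SimConfig(
        n_genes=300,
        n_mirnas=60,
        n_tumor=40,
        n_control=20,
        seed=7,
    )
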