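import numpy as np
import pytest

from gaborvessel.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at defaults (seed 0), shared across tests."""
    return generate_phantom(PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def small_phantom():
    """A 128x128 phantom, cheap enough for end-to-end pipeline tests."""
    return generate_phantom(PhantomConfig(height=128, width=128, n_trees=2, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
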