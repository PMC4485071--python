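import numpy as np
import pytest

from netconnkit.connectivity import ConnectivityMatrix
from netconnkit.preprocess import BoldTimeSeries
from netconnkit.synthetic import gen_toy_graphs


@pytest.fixture(scope="session")
def toys():
    """Deterministic named fixture graphs with known metric values."""
    return gen_toy_graphs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_block(rng):
    """A 50 x 8 random time-series block at dt = 2 s."""
    return BoldTimeSeries(rng.standard_normal((50, 8)), 2.0)


def random_connectivity(rng, n=10):
    """A valid random connectivity matrix (symmetric, zero diagonal)."""
    x = rng.standard_normal((n + 20, n))
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(np.clip(r, -1, 1))


@pytest.fixture
def conn10(rng):
    return random_connectivity(rng, 10)
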