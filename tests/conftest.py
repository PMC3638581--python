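import numpy as np
import pytest

from herbnet import network_from_edges, qly_fixture


@pytest.fixture(scope="session")
def qly():
    return qly_fixture()


@pytest.fixture
def chain_net():
    """A - B - C path graph."""
    return network_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_bits(rng, n=64, p=0.5):
    return (rng.random(n) < p).astype(np.uint8)
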