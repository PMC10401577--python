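import numpy as np
import pytest

from crysvib.synthetic import make_toy_molecular_crystal


@pytest.fixture(scope="session")
def toy_system():
    """Two-molecule toy polar crystal shared across read-only tests."""
    return make_toy_molecular_crystal(n_molecules=2, seed=1)


@pytest.fixture(scope="session")
def toy_system_1mol():
    return make_toy_molecular_crystal(n_molecules=1, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
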