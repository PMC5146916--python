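import numpy as np
import pytest

from poretrans import build_membrane, build_polymer, carve_pore
from poretrans.forcefield import ForceFieldParams, System
from poretrans.validation import _random_small_system


@pytest.fixture(scope="session")
def default_membrane():
    """The default 5488-site sheet for the N = 49 chain."""
    return build_membrane(n=16)


@pytest.fixture(scope="session")
def small_pore_membrane(default_membrane):
    return carve_pore(default_membrane, 1.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_system_factory():
    """Factory of randomized <=30-bead polymer+membrane systems."""
    rng = np.random.default_rng(99)

    def make():
        return _random_small_system(rng)

    return make


@pytest.fixture(scope="session")
def free_chain_system():
    top, pos = build_polymer(4, seed=11)
    return System(top, None, ForceFieldParams()), pos
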