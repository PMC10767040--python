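import numpy as np
import pytest

from helimorph.lattice import VP39_LATTICE, Lattice2D
from helimorph.synthetic import make_pseudo_unit


@pytest.fixture(scope="session")
def lattice() -> Lattice2D:
    """The printed nucleocapsid 2D crystal lattice."""
    return VP39_LATTICE


@pytest.fixture(scope="session")
def pseudo_unit():
    """A small reproducible pseudo-atomic subunit."""
    return make_pseudo_unit(n_blobs=12, seed=7)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
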