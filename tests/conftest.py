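import numpy as np
import pytest

from dmnet.connectome import tile
from dmnet.fixtures import make_motion_motif
from dmnet.hexlattice import enumerate_hex


@pytest.fixture(scope="session")
def lattice4():
    return enumerate_hex(4)


@pytest.fixture(scope="session")
def motif():
    return make_motion_motif(radius=4)


@pytest.fixture(scope="session")
def motif_net(motif, lattice4):
    return tile(motif.spec, lattice4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
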