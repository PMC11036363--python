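import warnings

import numpy as np
import pytest

from polyxtal import MoleculeTopology, UnitCell, get_space_group
from polyxtal.crystal import CrystalState
from polyxtal.fixtures import make_lj_monatomic, make_rigid_ring

# overlapping symmetry images are expected in randomized search states
warnings.filterwarnings("ignore", message="overlapping symmetry images")


@pytest.fixture(scope="session")
def lj_system():
    return make_lj_monatomic()


@pytest.fixture(scope="session")
def ring_system():
    return make_rigid_ring()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_molecule():
    """A 4-atom chain with every bonded term type and partial charges."""
    return MoleculeTopology(
        ["C", "C", "O", "H"],
        [12.011, 12.011, 15.999, 1.008],
        [0.10, 0.10, 0.12, 0.02],
        [3.80, 3.80, 3.40, 2.90],
        [0.10, 0.10, -0.30, 0.10],
        bonds=[(0, 1, 300.0, 1.5), (1, 2, 350.0, 1.4), (2, 3, 400.0, 1.0)],
        angles=[(0, 1, 2, 80.0, 110.0), (1, 2, 3, 60.0, 105.0)],
        torsions=[(0, 1, 2, 3, [(1.2, 3, 0.0), (0.5, 1, 180.0)])],
    )


@pytest.fixture
def chain_state(small_molecule, rng):
    coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [2.1, 1.2, 0.3], [3.0, 1.1, 0.9]])
    coords = coords + rng.normal(0, 0.05, coords.shape)
    cell = UnitCell(7.5, 8.0, 9.0, 90.0, 95.0, 90.0)
    return CrystalState(small_molecule, coords, cell, get_space_group("P21/c"), 0.63)
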