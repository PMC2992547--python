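import numpy as np
import pytest

from moeconf.chem_io import MoleculeRecord
from moeconf.torsion_geometry import Conformation
from moeconf.fixtures_and_cli import FixtureSpec, make_fixture


def _tetrahedral_methane(center, scale=1.09):
    c = np.asarray(center, dtype=float)
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    return [c + scale * d for d in dirs]


@pytest.fixture(scope="session")
def two_methanes():
    """Two CH4 fragments 20 A apart (asymptotic-vdw fixture)."""
    elements, coords, bonds = [], [], []
    for frag, center in enumerate([(0.0, 0.0, 0.0), (20.0, 0.0, 0.0)]):
        c_idx = len(elements)
        elements.append("C")
        coords.append(np.asarray(center, dtype=float))
        for h in _tetrahedral_methane(center):
            elements.append("H")
            coords.append(h)
            bonds.append((c_idx, len(elements) - 1, "1"))
    return MoleculeRecord(
        name="two-methanes", elements=elements, coords=np.array(coords), bonds=bonds
    )


@pytest.fixture(scope="session")
def benzene():
    """Hand-coded benzene: regular hexagon, C-C 1.39 A, C-H 1.09 A."""
    elements, coords, bonds = [], [], []
    r_c, r_h = 1.39, 1.39 + 1.09
    for i in range(6):
        a = np.pi / 3 * i
        elements.append("C")
        coords.append([r_c * np.cos(a), r_c * np.sin(a), 0.0])
    for i in range(6):
        a = np.pi / 3 * i
        elements.append("H")
        coords.append([r_h * np.cos(a), r_h * np.sin(a), 0.0])
        bonds.append((i, 6 + i, "1"))
    for i in range(6):
        bonds.append((i, (i + 1) % 6, "ar"))
    return MoleculeRecord(
        name="benzene",
        elements=elements,
        coords=np.array(coords),
        bonds=bonds,
        atom_types=["C.ar"] * 6 + ["H"] * 6,
    )


@pytest.fixture(scope="session")
def butane():
    """Butane from the deterministic fixture generator (4 heavy atoms)."""
    mol, conf = make_fixture(FixtureSpec(n_heavy_atoms=4, topology="chain", seed=42,
                                         heteroatom_fraction=0.0))
    return mol, conf


@pytest.fixture(scope="session")
def pentane():
    mol, conf = make_fixture(FixtureSpec(n_heavy_atoms=5, topology="chain", seed=7,
                                         heteroatom_fraction=0.0))
    return mol, conf


@pytest.fixture(scope="session")
def chain8():
    mol, conf = make_fixture(FixtureSpec(n_heavy_atoms=8, topology="chain", seed=3))
    return mol, conf


@pytest.fixture(scope="session")
def flexible12():
    """Chain with >=8 rotatable bonds for diversity-contrast tests."""
    mol, conf = make_fixture(FixtureSpec(n_heavy_atoms=12, topology="chain", seed=5))
    return mol, conf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
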