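import numpy as np
import pytest

from moeconf.chem_io import MoleculeRecord
from moeconf.torsion_geometry import (
    Conformation,
    GeometryError,
    best_fit_rmsd,
    geometric_dissimilarity,
    measure_dihedral,
    measure_torsions,
    perceive_rotatable_bonds,
    radius_of_gyration,
    set_torsions,
    superpose_rmsd,
    wrap_angle,
)

from .oracles import exhaustive_heavy_mappings, quaternion_rmsd, zmatrix_chain


def _bond_lengths(mol, coords):
    return np.array([np.linalg.norm(coords[i] - coords[j]) for i, j, _ in mol.bonds])


def _bond_angles(mol, coords):
    adj = {}
    for i, j, _ in mol.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    angles = []
    for j, nbrs in adj.items():
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                v1 = coords[nbrs[a]] - coords[j]
                v2 = coords[nbrs[b]] - coords[j]
                c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angles.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
    return np.array(angles)


def _random_rigid(coords, rng):
    from scipy.spatial.transform import Rotation

    r = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return coords @ r.T + t


# ---------------------------------------------------------------------------
# rotatable-bond perception
# ---------------------------------------------------------------------------


def test_butane_one_rotatable(butane):
    mol, _ = butane
    rot = perceive_rotatable_bonds(mol)
    assert len(rot) == 1
    heavy = set(mol.heavy_atom_indices)
    assert set(rot[0].axis) <= heavy


def test_ethane_zero_rotatable():
    coords = zmatrix_chain([1.53], [], [])
    elements = ["C", "C"] + ["H"] * 6
    hs = [
        [-0.5, 0.9, 0.3], [-0.5, -0.9, 0.3], [-0.5, 0.0, -1.0],
        [2.0, 0.9, 0.3], [2.0, -0.9, 0.3], [2.0, 0.0, -1.0],
    ]
    allc = np.vstack([coords, np.array(hs)])
    bonds = [(0, 1, "1")] + [(0, i, "1") for i in (2, 3, 4)] + [(1, i, "1") for i in (5, 6, 7)]
    mol = MoleculeRecord(name="ethane", elements=elements, coords=allc, bonds=bonds)
    assert perceive_rotatable_bonds(mol) == []


def test_benzene_zero_rotatable(benzene):
    assert perceive_rotatable_bonds(benzene) == []


def test_amide_excluded():
    # CH3-C(=O)-N(H)-CH3: the C-N bond must not be rotatable; C-C and N-C are
    elements = ["C", "C", "O", "N", "C"]
    coords = np.array(
        [[0, 0, 0], [1.5, 0, 0], [2.1, 1.0, 0], [2.2, -1.2, 0], [3.6, -1.3, 0]], dtype=float
    )
    bonds = [(0, 1, "1"), (1, 2, "2"), (1, 3, "1"), (3, 4, "1")]
    mol = MoleculeRecord(name="amide", elements=elements, coords=coords, bonds=bonds)
    axes = {tuple(sorted(rb.axis)) for rb in perceive_rotatable_bonds(mol)}
    assert (1, 3) not in axes


def test_moving_set_partition(chain8):
    mol, _ = chain8
    for rb in perceive_rotatable_bonds(mol):
        j, k = rb.axis
        assert j not in rb.moving_set
        assert k in rb.moving_set
        static = set(range(mol.n_atoms)) - rb.moving_set
        assert len(rb.moving_set) <= len(static)


def test_disconnected_graph_errors(two_methanes):
    with pytest.raises(GeometryError):
        perceive_rotatable_bonds(two_methanes)


# ---------------------------------------------------------------------------
# torsion driving
# ---------------------------------------------------------------------------


def test_set_torsions_identity(chain8):
    mol, conf = chain8
    rot = perceive_rotatable_bonds(mol)
    tv = measure_torsions(mol, conf, rot)
    out = set_torsions(mol, conf, tv, rot)
    assert np.allclose(out.coords, conf.coords, atol=1e-9)


def test_set_torsions_preserves_internal_geometry(chain8, rng):
    mol, conf = chain8
    rot = perceive_rotatable_bonds(mol)
    for _ in range(20):
        tv = rng.uniform(-180, 180, len(rot))
        out = set_torsions(mol, conf, tv, rot)
        assert np.allclose(
            _bond_lengths(mol, out.coords), _bond_lengths(mol, conf.coords), atol=1e-6
        )
        assert np.allclose(
            _bond_angles(mol, out.coords), _bond_angles(mol, conf.coords), atol=1e-4
        )


def test_set_measure_round_trip(chain8, rng):
    mol, conf = chain8
    rot = perceive_rotatable_bonds(mol)
    for _ in range(100):
        tv = rng.uniform(-180, 180, len(rot))
        out = set_torsions(mol, conf, tv, rot)
        back = measure_torsions(mol, out, rot)
        assert np.max(np.abs(wrap_angle(back - tv))) < 1e-4


def test_length_mismatch_errors(chain8):
    mol, conf = chain8
    with pytest.raises(ValueError):
        set_torsions(mol, conf, [0.0])


def test_butane_anti_distance_matches_zmatrix_oracle(butane):
    mol, conf = butane
    rot = perceive_rotatable_bonds(mol)
    assert len(rot) == 1
    i, j, k, l = rot[0].dihedral_quad
    b = conf.coords
    lens = [np.linalg.norm(b[j] - b[i]), np.linalg.norm(b[k] - b[j]), np.linalg.norm(b[l] - b[k])]

    def ang(p, q, r):
        v1, v2 = b[p] - b[q], b[r] - b[q]
        return np.degrees(np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))

    oracle = zmatrix_chain(lens, [ang(i, j, k), ang(j, k, l)], [180.0])
    expected = np.linalg.norm(oracle[3] - oracle[0])
    anti = set_torsions(mol, conf, [180.0], rot)
    got = np.linalg.norm(anti.coords[l] - anti.coords[i])
    assert got == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# dihedral measurement
# ---------------------------------------------------------------------------


def test_planar_cis_is_zero():
    coords = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
    assert measure_dihedral(coords, (0, 1, 2, 3)) == pytest.approx(0.0, abs=1e-10)


def test_planar_trans_wraps_to_minus_180():
    coords = np.array([[-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
    assert measure_dihedral(coords, (0, 1, 2, 3)) == pytest.approx(-180.0, abs=1e-10)


def test_collinear_quad_errors():
    coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
    with pytest.raises(GeometryError):
        measure_dihedral(coords, (0, 1, 2, 3))


# ---------------------------------------------------------------------------
# gyration radius
# ---------------------------------------------------------------------------


def test_rg_single_heavy_atom(two_methanes):
    sub = MoleculeRecord(
        name="methane",
        elements=["C", "H"],
        coords=np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 3.0]]),
        bonds=[(0, 1, "1")],
    )
    assert radius_of_gyration(Conformation(coords=sub.coords), sub) == 0.0


def test_rg_two_heavy_atoms_is_half_distance():
    d = 2.75
    mol = MoleculeRecord(
        name="duo",
        elements=["C", "C"],
        coords=np.array([[0.0, 0, 0], [d, 0, 0]]),
        bonds=[(0, 1, "1")],
    )
    assert radius_of_gyration(Conformation(coords=mol.coords), mol) == pytest.approx(d / 2)


def test_rg_square_closed_form():
    s = 1.7
    coords = np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]], dtype=float)
    mol = MoleculeRecord(
        name="square",
        elements=["C"] * 4,
        coords=coords,
        bonds=[(0, 1, "1"), (1, 2, "1"), (2, 3, "1"), (3, 0, "1")],
    )
    assert radius_of_gyration(Conformation(coords=coords), mol) == pytest.approx(s / np.sqrt(2))


def test_rg_rigid_motion_invariant(chain8, rng):
    mol, conf = chain8
    base = radius_of_gyration(conf, mol)
    for _ in range(5):
        moved = _random_rigid(conf.coords, rng)
        assert radius_of_gyration(Conformation(coords=moved), mol) == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# superposition RMSD
# ---------------------------------------------------------------------------


def test_rmsd_identical_zero(chain8):
    mol, conf = chain8
    pairs = [(i, i) for i in mol.heavy_atom_indices]
    assert superpose_rmsd(conf.coords, conf.coords, pairs) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_rigid_invariance(chain8, rng):
    mol, conf = chain8
    pairs = [(i, i) for i in mol.heavy_atom_indices]
    moved = _random_rigid(conf.coords, rng)
    assert superpose_rmsd(conf.coords, moved, pairs) == pytest.approx(0.0, abs=1e-6)


def test_rmsd_matches_quaternion_oracle(rng):
    for _ in range(20):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        got = superpose_rmsd(a, b, [(i, i) for i in range(5)])
        assert got == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)


def test_rmsd_symmetric(rng):
    a = rng.normal(size=(6, 3))
    b = rng.normal(size=(6, 3))
    pairs = [(i, i) for i in range(6)]
    assert superpose_rmsd(a, b, pairs) == pytest.approx(superpose_rmsd(b, a, pairs), abs=1e-10)


def test_rmsd_too_few_pairs_errors(rng):
    a = rng.normal(size=(2, 3))
    with pytest.raises(GeometryError):
        superpose_rmsd(a, a, [(0, 0), (1, 1)])


def test_rmsd_collinear_errors():
    a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
    with pytest.raises(GeometryError):
        superpose_rmsd(a, a, [(i, i) for i in range(4)])


# ---------------------------------------------------------------------------
# best-fit (symmetry-corrected) RMSD
# ---------------------------------------------------------------------------


def test_benzene_ring_rotation_is_zero(benzene):
    # relabel the carbons by one ring step: a pure symmetry operation
    perm = list(range(12))
    for i in range(6):
        perm[i] = (i + 1) % 6
        perm[6 + i] = 6 + (i + 1) % 6
    rotated = benzene.coords[perm]
    assert best_fit_rmsd(rotated, benzene.coords, benzene) == pytest.approx(0.0, abs=1e-9)


def test_asymmetric_molecule_equals_identity(chain8, rng):
    mol, conf = chain8
    # heteroatom-containing chain is asymmetric; best-fit == identity mapping
    rot = perceive_rotatable_bonds(mol)
    other = set_torsions(mol, conf, rng.uniform(-180, 180, len(rot)), rot)
    ident = superpose_rmsd(
        other.coords, conf.coords, [(i, i) for i in mol.heavy_atom_indices]
    )
    assert best_fit_rmsd(other, conf, mol) == pytest.approx(ident, abs=1e-9)


def test_chain_reversal_beats_identity(pentane):
    mol, conf = pentane
    heavy = mol.heavy_atom_indices
    rot = perceive_rotatable_bonds(mol)
    asym = set_torsions(mol, conf, [60.0, 170.0], rot)
    # relabel heavy chain end-for-end (C1<->C5, C2<->C4); point set unchanged
    perm = np.arange(mol.n_atoms)
    perm[heavy[0]], perm[heavy[4]] = heavy[4], heavy[0]
    perm[heavy[1]], perm[heavy[3]] = heavy[3], heavy[1]
    reversed_coords = asym.coords.copy()
    reversed_coords[list(perm)] = asym.coords
    ident = superpose_rmsd(reversed_coords, asym.coords, [(i, i) for i in heavy])
    best = best_fit_rmsd(reversed_coords, asym.coords, mol)
    assert best < ident
    assert best == pytest.approx(0.0, abs=1e-9)
    # cross-check with the exhaustive mapping oracle
    mappings = exhaustive_heavy_mappings(mol.elements, mol.bonds, heavy)
    oracle = min(
        quaternion_rmsd(reversed_coords[[m[i] for i in heavy]], asym.coords[heavy])
        for m in mappings
    )
    assert best == pytest.approx(oracle, abs=1e-8)


def test_best_fit_never_exceeds_identity(chain8, rng):
    mol, conf = chain8
    rot = perceive_rotatable_bonds(mol)
    heavy_pairs = [(i, i) for i in mol.heavy_atom_indices]
    for _ in range(10):
        other = set_torsions(mol, conf, rng.uniform(-180, 180, len(rot)), rot)
        assert best_fit_rmsd(other, conf, mol) <= superpose_rmsd(
            other.coords, conf.coords, heavy_pairs
        ) + 1e-12


# ---------------------------------------------------------------------------
# geometric dissimilarity
# ---------------------------------------------------------------------------


def test_gd_self_is_zero(chain8):
    mol, conf = chain8
    assert geometric_dissimilarity(conf, conf, mol) == pytest.approx(0.0, abs=1e-9)


def test_gd_symmetric_nonnegative(chain8, rng):
    mol, conf = chain8
    rot = perceive_rotatable_bonds(mol)
    for _ in range(5):
        a = set_torsions(mol, conf, rng.uniform(-180, 180, len(rot)), rot)
        b = set_torsions(mol, conf, rng.uniform(-180, 180, len(rot)), rot)
        gd_ab = geometric_dissimilarity(a, b, mol)
        gd_ba = geometric_dissimilarity(b, a, mol)
        assert gd_ab >= 0
        assert gd_ab == pytest.approx(gd_ba, abs=1e-9)


def test_gd_matches_quaternion_oracle(butane):
    mol, conf = butane
    rot = perceive_rotatable_bonds(mol)
    tv = measure_torsions(mol, conf, rot)
    flipped = set_torsions(mol, conf, wrap_angle(tv + 180.0), rot)
    heavy = mol.heavy_atom_indices
    expected = quaternion_rmsd(flipped.coords[heavy], conf.coords[heavy])
    assert geometric_dissimilarity(flipped, conf, mol) == pytest.approx(expected, abs=1e-8)
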