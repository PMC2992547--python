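"""Torsion-space geometry: rotatable-bond perception, dihedral driving under
fixed bond lengths/angles, and the geometric observables used as search
objectives and benchmark metrics (gyration radius, geometric dissimilarity,
symmetry-aware best-fit RMSD).

All RMSD / Rg / dissimilarity computations use heavy atoms with unit weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .chem_io import MoleculeRecord

__all__ = [
    "RotatableBond",
    "Conformation",
    "perceive_rotatable_bonds",
    "set_torsions",
    "measure_torsions",
    "measure_dihedral",
    "radius_of_gyration",
    "superpose_rmsd",
    "best_fit_rmsd",
    "geometric_dissimilarity",
    "heavy_graph_automorphisms",
    "wrap_angle",
    "GeometryError",
]

logger = logging.getLogger(__name__)

AUTOMORPHISM_CAP = 10_000


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RotatableBond:
    """An acyclic single bond driven during sampling.

    ``axis`` is ordered (j, k) with k on the moving side; ``dihedral_quad``
    (i, j, k, l) defines the measured angle; ``moving_set`` holds the atom
    indices displaced when the torsion changes.
    """

    axis: tuple[int, int]
    dihedral_quad: tuple[int, int, int, int]
    moving_set: frozenset[int]


@dataclass
class Conformation:
    """Cartesian coordinates plus cached per-conformer bookkeeping."""

    coords: np.ndarray
    torsions: np.ndarray | None = None
    energy_terms: object | None = None  # EnergyBreakdown, set by backends
    objective_values: np.ndarray | None = None
    minimized: bool = False
    source_ff: str | None = None
    min_steps: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def copy(self) -> "Conformation":
        return replace(
            self,
            coords=self.coords.copy(),
            torsions=None if self.torsions is None else self.torsions.copy(),
        )

    @property
    def filter_energy(self) -> float:
        """Energy used for window filtering (vdw + torsion, or total after
        minimization)."""
        if self.energy_terms is None:
            raise ValueError("energy terms not evaluated")
        if self.minimized:
            return self.energy_terms.total_no_elec
        return self.energy_terms.vdw + self.energy_terms.torsion


def wrap_angle(deg):
    """Wrap angle(s) in degrees to [-180, 180)."""
    return (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0


def _graph(mol: MoleculeRecord) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    for i, j, order in mol.bonds:
        g.add_edge(i, j, order=order)
    return g


def _is_amide(mol: MoleculeRecord, g: nx.Graph, i: int, j: int) -> bool:
    """C-N single bond where the carbon carries a double-bonded O."""
    for c, n in ((i, j), (j, i)):
        if mol.elements[c] == "C" and mol.elements[n] == "N":
            for nb in g.neighbors(c):
                if mol.elements[nb] == "O" and g.edges[c, nb]["order"] == "2":
                    return True
    return False


def perceive_rotatable_bonds(mol: MoleculeRecord) -> list[RotatableBond]:
    """Deterministic rotatable-bond list for a connected molecular graph.

    A bond is rotatable iff it is acyclic (a bridge), of single order (amide
    C-N excluded), and each endpoint has at least one heavy neighbour besides
    the other endpoint, so that rotation moves heavy atoms on both sides.
    """
    g = _graph(mol)
    if mol.n_atoms > 1 and not nx.is_connected(g):
        raise GeometryError("molecular graph is disconnected")
    bridges = set(frozenset(e) for e in nx.bridges(g)) if g.number_of_edges() else set()

    heavy = set(mol.heavy_atom_indices)
    result: list[RotatableBond] = []
    for i, j, order in mol.bonds:
        a, b = (i, j) if i < j else (j, i)
        if order != "1" or frozenset((a, b)) not in bridges:
            continue
        if _is_amide(mol, g, a, b):
            continue
        heavy_nb_a = [n for n in g.neighbors(a) if n != b and n in heavy]
        heavy_nb_b = [n for n in g.neighbors(b) if n != a and n in heavy]
        if not heavy_nb_a or not heavy_nb_b:
            continue
        # moving side = smaller side; orient axis (j, k) with k moving
        h = g.copy()
        h.remove_edge(a, b)
        side_b = nx.node_connected_component(h, b)
        side_a = nx.node_connected_component(h, a)
        if len(side_b) <= len(side_a):
            jj, kk, moving = a, b, side_b
        else:
            jj, kk, moving = b, a, side_a
        ref_j = min(n for n in g.neighbors(jj) if n != kk and n in heavy)
        ref_k = min(n for n in g.neighbors(kk) if n != jj and n in heavy)
        result.append(
            RotatableBond(
                axis=(jj, kk),
                dihedral_quad=(ref_j, jj, kk, ref_k),
                moving_set=frozenset(moving),
            )
        )
    result.sort(key=lambda rb: tuple(sorted(rb.axis)))
    return result


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # np.cross has large call overhead for single 3-vectors (hot path)
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def measure_dihedral(coords: np.ndarray, quad: Sequence[int]) -> float:
    """Signed dihedral angle (degrees in [-180, 180)) for atoms i-j-k-l."""
    i, j, k, l = quad
    coords = np.asarray(coords, dtype=float)
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    if n1 @ n1 < 1e-20 or n2 @ n2 < 1e-20:
        raise GeometryError(f"dihedral undefined: collinear atoms in quad {tuple(quad)}")
    m1 = _cross3(n1, b2 / np.sqrt(b2 @ b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def measure_torsions(
    mol: MoleculeRecord,
    conf: Conformation | np.ndarray,
    rotatable: list[RotatableBond] | None = None,
) -> np.ndarray:
    """Dihedral value per rotatable bond, in perception order."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    if rotatable is None:
        rotatable = perceive_rotatable_bonds(mol)
    return np.array([measure_dihedral(coords, rb.dihedral_quad) for rb in rotatable])


def _rotation_matrix(axis_unit: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    ux, uy, uz = axis_unit
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + ux * ux * C, ux * uy * C - uz * s, ux * uz * C + uy * s],
            [uy * ux * C + uz * s, c + uy * uy * C, uy * uz * C - ux * s],
            [uz * ux * C - uy * s, uz * uy * C + ux * s, c + uz * uz * C],
        ]
    )


def moving_index_arrays(rotatable: Sequence[RotatableBond]) -> list[np.ndarray]:
    """Per-bond sorted moving-set index arrays (axis atom k excluded)."""
    return [
        np.fromiter(sorted(rb.moving_set - {rb.axis[1]}), dtype=np.intp)
        for rb in rotatable
    ]


def apply_torsions(
    base_coords: np.ndarray,
    rotatable: Sequence[RotatableBond],
    base_torsions: np.ndarray,
    targets: np.ndarray,
    moving_arrays: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Rotate each bond's moving set from its known base dihedral to the
    target value; returns new coordinates.

    A bond's dihedral is unaffected by the other bonds' rotations (the axis
    atoms stay on the rotation axis), so the per-bond delta can be computed
    from the base torsions without re-measuring.
    """
    coords = base_coords.copy()
    if moving_arrays is None:
        moving_arrays = moving_index_arrays(rotatable)
    deltas = np.radians(
        (np.asarray(targets, dtype=float) - np.asarray(base_torsions, dtype=float) + 180.0)
        % 360.0
        - 180.0
    )
    for rb, idx, delta in zip(rotatable, moving_arrays, deltas):
        if abs(delta) < 1e-12 or len(idx) == 0:
            continue
        j, k = rb.axis
        axis = coords[k] - coords[j]
        axis /= np.sqrt(axis @ axis)
        # rotating the k-side by -delta about the j->k axis increases the
        # measured i-j-k-l dihedral by +delta
        rot = _rotation_matrix(axis, -delta)
        pivot = coords[k]
        coords[idx] = (coords[idx] - pivot) @ rot.T + pivot
    return coords


def set_torsions(
    mol: MoleculeRecord,
    base: Conformation,
    torsions: Sequence[float] | np.ndarray,
    rotatable: list[RotatableBond] | None = None,
) -> Conformation:
    """Return a new conformation with the given dihedral values.

    Only atoms in each bond's moving set are rotated, so every bond length
    and bond angle of ``base`` is preserved exactly.
    """
    if rotatable is None:
        rotatable = perceive_rotatable_bonds(mol)
    tv = np.asarray(torsions, dtype=float)
    if tv.shape != (len(rotatable),):
        raise ValueError(
            f"torsion vector length {tv.shape} != rotatable-bond count {len(rotatable)}"
        )
    base_tv = np.array(
        [measure_dihedral(base.coords, rb.dihedral_quad) for rb in rotatable]
    )
    coords = apply_torsions(base.coords, rotatable, base_tv, tv)
    return Conformation(coords=coords, torsions=wrap_angle(tv))


def radius_of_gyration(conf: Conformation | np.ndarray, mol: MoleculeRecord) -> float:
    """Unit-weight heavy-atom radius of gyration (Angstrom)."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    heavy = mol.heavy_atom_indices
    if not heavy:
        raise GeometryError("no heavy atoms")
    x = coords[heavy]
    centered = x - x.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def superpose_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    atom_map: Sequence[tuple[int, int]],
) -> float:
    """Least-squares rigid-body-minimised RMSD over the mapped atom pairs.

    Kabsch algorithm with proper-rotation correction; symmetric in its
    arguments and invariant under rigid motion of either input.
    """
    pairs = list(atom_map)
    if len(pairs) < 3:
        raise GeometryError("superposition needs at least 3 atom pairs")
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    a = np.asarray(coords_a, dtype=float)[ia]
    b = np.asarray(coords_b, dtype=float)[ib]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    # collinearity check via 3x3 covariance eigenvalues (cheap; runs in the
    # sampler's hot path)
    for x in (a, b):
        ev = np.linalg.eigvalsh(x.T @ x)
        if ev[1] <= 1e-10 * max(ev[2], 1.0):
            raise GeometryError("degenerate (collinear) reference for superposition")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    e0 = np.sum(a**2) + np.sum(b**2)
    msd = max(0.0, (e0 - 2.0 * (s[0] + s[1] + d * s[2])) / len(pairs))
    return float(np.sqrt(msd))


class ReferenceSuperposer:
    """Precomputed-reference Kabsch RMSD for repeated comparisons against one
    fixed structure over a fixed atom subset (hot path of GD evaluation)."""

    def __init__(self, ref_coords: np.ndarray, indices: Sequence[int]):
        self.idx = np.asarray(indices, dtype=np.intp)
        if len(self.idx) < 3:
            raise GeometryError("superposition needs at least 3 atom pairs")
        b = np.asarray(ref_coords, dtype=float)[self.idx]
        b = b - b.mean(axis=0)
        ev = np.linalg.eigvalsh(b.T @ b)
        if ev[1] <= 1e-10 * max(ev[2], 1.0):
            raise GeometryError("degenerate (collinear) reference for superposition")
        self.b = b
        self.e0b = float(np.sum(b * b))

    def rmsd(self, coords: np.ndarray) -> float:
        a = coords[self.idx]
        a = a - a.mean(axis=0)
        h = a.T @ self.b
        s = np.linalg.svd(h, compute_uv=False)
        d = np.sign(np.linalg.det(h)) if s[2] > 1e-12 else 1.0
        e0 = float(np.sum(a * a)) + self.e0b
        msd = max(0.0, (e0 - 2.0 * (s[0] + s[1] + d * s[2])) / len(self.idx))
        return float(np.sqrt(msd))


_auto_cache: dict[int, tuple[MoleculeRecord, list[dict[int, int]]]] = {}


def heavy_graph_automorphisms(mol: MoleculeRecord, cap: int = AUTOMORPHISM_CAP) -> list[dict[int, int]]:
    """Element- and bond-order-preserving automorphisms of the heavy-atom graph.

    Enumeration is capped; on overflow only the identity mapping is returned
    (with a warning), which keeps best-fit RMSD well-defined.
    """
    cached = _auto_cache.get(id(mol))
    if cached is not None and cached[0] is mol:
        return cached[1]
    heavy = mol.heavy_atom_indices
    g = nx.Graph()
    for i in heavy:
        g.add_node(i, el=mol.elements[i])
    heavy_set = set(heavy)
    for i, j, order in mol.bonds:
        if i in heavy_set and j in heavy_set:
            g.add_edge(i, j, order=order)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda x, y: x["el"] == y["el"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
    autos: list[dict[int, int]] = []
    overflow = False
    for mapping in matcher.isomorphisms_iter():
        autos.append(dict(mapping))
        if len(autos) > cap:
            overflow = True
            break
    if overflow:
        logger.warning(
            "automorphism enumeration exceeded cap (%d) for %s; using identity only",
            cap,
            mol.name,
        )
        autos = [{i: i for i in heavy}]
    _auto_cache[id(mol)] = (mol, autos)
    return autos


def best_fit_rmsd(
    conf: Conformation | np.ndarray,
    ref: Conformation | np.ndarray,
    mol: MoleculeRecord,
) -> float:
    """Symmetry-corrected heavy-atom RMSD: minimum of superpose_rmsd over the
    automorphisms of the heavy-atom graph."""
    ca = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    cb = ref.coords if isinstance(ref, Conformation) else np.asarray(ref)
    best = np.inf
    for mapping in heavy_graph_automorphisms(mol):
        pairs = [(mapping[i], i) for i in mol.heavy_atom_indices]
        best = min(best, superpose_rmsd(ca, cb, pairs))
    return best


def geometric_dissimilarity(
    conf: Conformation | np.ndarray,
    input_conf: Conformation | np.ndarray,
    mol: MoleculeRecord,
) -> float:
    """Heavy-atom RMSD to the input conformation under the identity mapping."""
    ca = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    cb = input_conf.coords if isinstance(input_conf, Conformation) else np.asarray(input_conf)
    pairs = [(i, i) for i in mol.heavy_atom_indices]
    return superpose_rmsd(ca, cb, pairs)
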