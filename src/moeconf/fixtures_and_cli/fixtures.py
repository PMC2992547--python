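"""Synthetic drug-like test molecules with controllable flexibility.

Molecules are C/N/O heavy-atom trees (optionally containing one saturated
ring), hydrogen-completed and embedded to an idealized sp3 3D geometry with
RDKit's distance-geometry embedder; everything is deterministic in the seed.
A planted target conformation (set of torsions applied to the embedded
geometry) serves as the "bioactive" reference in synthetic benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..chem_io import MoleculeRecord
from ..torsion_geometry import Conformation, measure_torsions, perceive_rotatable_bonds, set_torsions

__all__ = ["FixtureSpec", "make_fixture", "make_fixture_set", "plant_target"]


@dataclass(frozen=True)
class FixtureSpec:
    n_heavy_atoms: int
    topology: str = "chain"  # "chain" | "branched" | "ring"
    seed: int = 0
    heteroatom_fraction: float = 0.15
    planted_torsions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_heavy_atoms < 2:
            raise ValueError("need at least 2 heavy atoms")
        if self.topology not in ("chain", "branched", "ring"):
            raise ValueError(f"unknown topology {self.topology!r}")


_RING_SIZE = 6


def _heavy_graph(spec: FixtureSpec, rng: np.random.Generator):
    """(elements, bonds) for the heavy-atom skeleton."""
    n = spec.n_heavy_atoms
    bonds: list[tuple[int, int]] = []
    if spec.topology == "chain":
        bonds = [(i, i + 1) for i in range(n - 1)]
    elif spec.topology == "branched":
        # random tree, max heavy degree 3 (leaves room for hydrogens)
        degree = [0] * n
        for i in range(1, n):
            candidates = [j for j in range(i) if degree[j] < 3]
            # bias toward recent atoms so chains with occasional branches emerge
            weights = np.array([1.0 + 3.0 * (j / max(1, i - 1)) for j in candidates])
            parent = candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))]
            bonds.append((parent, i))
            degree[parent] += 1
            degree[i] += 1
    else:  # ring
        if n < _RING_SIZE + 1:
            raise ValueError(
                f"ring topology needs at least {_RING_SIZE + 1} heavy atoms, got {n}"
            )
        bonds = [(i, (i + 1) % _RING_SIZE) for i in range(_RING_SIZE)]
        bonds.append((0, _RING_SIZE))  # tail anchor
        bonds += [(i, i + 1) for i in range(_RING_SIZE, n - 1)]

    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)

    elements = ["C"] * n
    in_ring = set(range(_RING_SIZE)) if spec.topology == "ring" else set()
    n_hetero = int(round(spec.heteroatom_fraction * n))
    order = rng.permutation(n)
    placed = 0
    for idx in order:
        if placed >= n_hetero:
            break
        i = int(idx)
        if i in in_ring:
            continue
        if any(elements[j] != "C" for j in adj[i]):
            continue  # no adjacent heteroatoms
        deg = len(adj[i])
        sym = "N" if deg == 3 else ("O" if deg <= 2 and rng.random() < 0.5 else "N")
        if (sym == "O" and deg > 2) or (sym == "N" and deg > 3):
            continue
        elements[i] = sym
        placed += 1
    return elements, bonds


def make_fixture(spec: FixtureSpec) -> tuple[MoleculeRecord, Conformation]:
    """Build the molecule and its input conformation."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rng = np.random.default_rng(spec.seed)
    elements, bonds = _heavy_graph(spec, rng)

    rw = Chem.RWMol()
    for el in elements:
        rw.AddAtom(Chem.Atom(el))
    for i, j in bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    m = Chem.AddHs(m)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(spec.seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(m, params) != 0:
        raise RuntimeError(f"3D embedding failed for fixture seed={spec.seed}")

    coords = np.array(m.GetConformer().GetPositions(), dtype=float)
    rec_elements = [a.GetSymbol() for a in m.GetAtoms()]
    rec_bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), "1") for b in m.GetBonds()
    ]
    sybyl = {"C": "C.3", "N": "N.3", "O": "O.3", "H": "H"}
    record = MoleculeRecord(
        name=f"fixture-{spec.topology}-{spec.n_heavy_atoms}-s{spec.seed}",
        elements=rec_elements,
        coords=coords,
        bonds=rec_bonds,
        atom_types=[sybyl[el] for el in rec_elements],
    )
    rotatable = perceive_rotatable_bonds(record)
    conf = Conformation(coords=coords.copy())
    conf.torsions = measure_torsions(record, conf, rotatable)
    if spec.planted_torsions is not None:
        conf = set_torsions(record, conf, np.asarray(spec.planted_torsions), rotatable)
    return record, conf


def plant_target(
    mol: MoleculeRecord,
    base_conf: Conformation,
    target_torsions: Sequence[float] | np.ndarray,
) -> Conformation:
    """Reference ("bioactive") conformation at the given torsion values."""
    return set_torsions(mol, base_conf, np.asarray(target_torsions, dtype=float))


def _low_energy_target(
    mol: MoleculeRecord,
    input_conf: Conformation,
    n_rot: int,
    rng: np.random.Generator,
    n_draws: int = 30,
) -> Conformation:
    """Pick the lowest-strain of several random torsion plantings.

    Reference conformations stand in for protein-bound ligand geometries,
    which are energetically accessible; an unfiltered random torsion vector
    is frequently clashed and would make the benchmark physically
    meaningless.
    """
    from ..energy_backends import get_backend

    model = get_backend("mmff94")
    best_conf, best_e = None, np.inf
    for _ in range(n_draws):
        tv = rng.uniform(-180.0, 180.0, size=n_rot)
        cand = plant_target(mol, input_conf, tv)
        terms = model.evaluate_terms(mol, cand)
        e = terms.vdw + terms.torsion
        if e < best_e:
            best_conf, best_e = cand, e
    return best_conf


def make_fixture_set(
    n_molecules: int,
    seed: int = 0,
    torsion_range: tuple[int, int] = (5, 15),
    topologies: Sequence[str] = ("chain", "branched"),
) -> list[tuple[MoleculeRecord, Conformation, Conformation]]:
    """Seeded benchmark set of (molecule, input conformation, planted
    reference) triples whose rotatable-bond counts fall in torsion_range.
    The planted reference is the lowest-strain of several torsion draws."""
    rng = np.random.default_rng(seed)
    out = []
    attempt = 0
    while len(out) < n_molecules:
        attempt += 1
        if attempt > 50 * n_molecules:
            raise RuntimeError("could not build the requested fixture set")
        topology = topologies[len(out) % len(topologies)]
        target_rot = int(rng.integers(torsion_range[0], torsion_range[1] + 1))
        # unbranched chain has n_heavy - 3 rotatable bonds; start there and probe
        n_heavy = target_rot + 3 + int(rng.integers(0, 3))
        spec = FixtureSpec(
            n_heavy_atoms=n_heavy,
            topology=topology,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            mol, input_conf = make_fixture(spec)
        except RuntimeError:
            continue
        rotatable = perceive_rotatable_bonds(mol)
        if not (torsion_range[0] <= len(rotatable) <= torsion_range[1]):
            continue
        reference = _low_energy_target(mol, input_conf, len(rotatable), rng)
        out.append((mol, input_conf, reference))
    return out
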