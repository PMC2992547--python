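"""Force-field quantities behind a backend-agnostic contract.

Two interchangeable parameterizations are provided:

* ``mmff94`` — MMFF94 terms from RDKit, with electrostatics disabled.
* ``tripos-like`` — a self-contained Lennard-Jones 12-6 + cosine-torsion
  approximation (plus harmonic bond/angle restraints to the reference
  geometry for Cartesian minimization), standing in for the Tripos force
  field, which has no open implementation.

"Filter energy" during sampling is vdw + torsion — the objectives the
sampler actually computes; after minimization the window re-applies on the
full no-electrostatics total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .chem_io import MoleculeRecord
from .torsion_geometry import Conformation

__all__ = [
    "EnergyBreakdown",
    "EnergyModel",
    "MMFF94Backend",
    "TriposLikeBackend",
    "AtomTypingError",
    "get_backend",
    "minimize_conformation",
    "VDW_CAP",
]

VDW_CAP = 1.0e6  # kcal/mol; keeps MOEA comparisons well-defined at clashes


class AtomTypingError(RuntimeError):
    """A backend could not assign parameters to the molecule's atoms."""


@dataclass(frozen=True)
class EnergyBreakdown:
    vdw: float
    torsion: float
    total_no_elec: float


def _cap(value: float) -> float:
    if not np.isfinite(value):
        return VDW_CAP
    return float(min(value, VDW_CAP))


class EnergyModel:
    """Contract: pure, deterministic, rigid-motion-invariant evaluation."""

    name: str = "abstract"

    def evaluate_terms(self, mol: MoleculeRecord, conf: Conformation) -> EnergyBreakdown:
        raise NotImplementedError

    def total_no_elec(self, mol: MoleculeRecord, coords: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, mol: MoleculeRecord, coords: np.ndarray) -> np.ndarray:
        """Gradient of total_no_elec, shape (n_atoms, 3), kcal/mol/A."""
        raise NotImplementedError


# ---------------------------------------------------------------------------
# MMFF94 via RDKit
# ---------------------------------------------------------------------------

_BOND_ORDER_MAP = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 12, "du": 1, "un": 1, "nc": 1}


def _to_rdkit(mol: MoleculeRecord):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for el in mol.elements:
        try:
            atom = Chem.Atom(el)
        except Exception as exc:  # unknown element symbol
            raise AtomTypingError(f"{mol.name}: unknown element {el!r}") from exc
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    order_map = {
        1: Chem.BondType.SINGLE,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
        12: Chem.BondType.AROMATIC,
    }
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, order_map[_BOND_ORDER_MAP.get(order, 1)])
    m = rw.GetMol()
    try:
        Chem.SanitizeMol(m)
    except Exception as exc:
        raise AtomTypingError(f"{mol.name}: sanitization failed ({exc})") from exc
    conf = Chem.Conformer(mol.n_atoms)
    for i, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m.AddConformer(conf, assignId=True)
    return m


class _MMFFContext:
    def __init__(self, mol: MoleculeRecord):
        self.record = mol
        self.rdmol = _to_rdkit(mol)
        self.ff_vdw = self._make_ff(only="VdW")
        self.ff_torsion = self._make_ff(only="Torsion")
        self.ff_total = self._make_ff(only=None)

    def _make_ff(self, only: str | None):
        from rdkit.Chem import AllChem

        props = AllChem.MMFFGetMoleculeProperties(self.rdmol)
        if props is None:
            raise AtomTypingError(f"{self.record.name}: MMFF94 atom typing failed")
        setters = {
            "Bond": props.SetMMFFBondTerm,
            "Angle": props.SetMMFFAngleTerm,
            "StretchBend": props.SetMMFFStretchBendTerm,
            "Oop": props.SetMMFFOopTerm,
            "Torsion": props.SetMMFFTorsionTerm,
            "VdW": props.SetMMFFVdWTerm,
        }
        if only is None:
            props.SetMMFFEleTerm(False)
        else:
            for term, setter in setters.items():
                setter(term == only)
            props.SetMMFFEleTerm(False)
        ff = AllChem.MMFFGetMoleculeForceField(self.rdmol, props)
        if ff is None:
            raise AtomTypingError(f"{self.record.name}: MMFF94 force field setup failed")
        return ff


class MMFF94Backend(EnergyModel):
    name = "mmff94"

    def __init__(self) -> None:
        self._cache: dict[int, _MMFFContext] = {}

    def _ctx(self, mol: MoleculeRecord) -> _MMFFContext:
        ctx = self._cache.get(id(mol))
        if ctx is None or ctx.record is not mol:
            ctx = _MMFFContext(mol)
            self._cache[id(mol)] = ctx
        return ctx

    def evaluate_terms(
        self, mol: MoleculeRecord, conf: Conformation | np.ndarray
    ) -> EnergyBreakdown:
        ctx = self._ctx(mol)
        coords = conf.coords if isinstance(conf, Conformation) else conf
        pos = np.asarray(coords, dtype=float).ravel().tolist()
        vdw = _cap(ctx.ff_vdw.CalcEnergy(pos))
        torsion = _cap(ctx.ff_torsion.CalcEnergy(pos))
        total = _cap(ctx.ff_total.CalcEnergy(pos))
        return EnergyBreakdown(vdw=vdw, torsion=torsion, total_no_elec=total)

    def total_no_elec(self, mol: MoleculeRecord, coords: np.ndarray) -> float:
        ctx = self._ctx(mol)
        return float(ctx.ff_total.CalcEnergy(np.asarray(coords, dtype=float).ravel().tolist()))

    def gradient(self, mol: MoleculeRecord, coords: np.ndarray) -> np.ndarray:
        ctx = self._ctx(mol)
        pos = np.asarray(coords, dtype=float).ravel().tolist()
        # CalcGrad alone can reuse stale internal state; an energy evaluation
        # at the same positions first makes it consistent
        ctx.ff_total.CalcEnergy(pos)
        g = ctx.ff_total.CalcGrad(pos)
        return np.asarray(g, dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Tripos-like approximation (LJ 12-6 + cosine torsions + harmonic restraints)
# ---------------------------------------------------------------------------

# R* (A), epsilon (kcal/mol) per element
_LJ_PARAMS = {
    "H": (1.20, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "S": (1.80, 0.314),
    "F": (1.47, 0.109),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
    "P": (1.80, 0.305),
}

_K_BOND = 300.0  # kcal/mol/A^2
_K_ANGLE = 60.0  # kcal/mol/rad^2


class _TriposContext:
    """Precomputed topology arrays; bond/angle equilibria from the record's
    reference geometry (the sampler holds them fixed anyway)."""

    def __init__(self, mol: MoleculeRecord):
        self.record = mol
        n = mol.n_atoms
        adj: list[set[int]] = [set() for _ in range(n)]
        order_of: dict[frozenset[int], str] = {}
        for i, j, order in mol.bonds:
            adj[i].add(j)
            adj[j].add(i)
            order_of[frozenset((i, j))] = order
        try:
            r_star = np.array([_LJ_PARAMS[el][0] for el in mol.elements])
            eps = np.array([_LJ_PARAMS[el][1] for el in mol.elements])
        except KeyError as exc:
            raise AtomTypingError(
                f"{mol.name}: no Lennard-Jones parameters for element {exc.args[0]!r}"
            ) from exc

        # nonbonded pairs: all pairs minus 1-2 and 1-3
        excluded = set()
        for i in range(n):
            for j in adj[i]:
                excluded.add(frozenset((i, j)))
                for k in adj[j]:
                    if k != i:
                        excluded.add(frozenset((i, k)))
        pairs = [
            (i, j)
            for i, j in itertools.combinations(range(n), 2)
            if frozenset((i, j)) not in excluded
        ]
        self.pair_idx = np.array(pairs, dtype=int).reshape(-1, 2)
        if len(pairs):
            pi, pj = self.pair_idx[:, 0], self.pair_idx[:, 1]
            self.pair_r0 = r_star[pi] + r_star[pj]
            self.pair_eps = np.sqrt(eps[pi] * eps[pj])

        # bonds / angles with reference equilibria
        self.bond_idx = np.array([[i, j] for i, j, _ in mol.bonds], dtype=int).reshape(-1, 2)
        ref = mol.coords
        if len(self.bond_idx):
            self.bond_r0 = np.linalg.norm(
                ref[self.bond_idx[:, 0]] - ref[self.bond_idx[:, 1]], axis=1
            )
        angles = []
        for j in range(n):
            for i, k in itertools.combinations(sorted(adj[j]), 2):
                angles.append((i, j, k))
        self.angle_idx = np.array(angles, dtype=int).reshape(-1, 3)
        if len(angles):
            self.angle_t0 = self._angles(ref)

        # proper torsions: every path i-j-k-l over every bond j-k
        torsions = []
        tor_params = []
        for (jk, order) in [((i, j), o) for i, j, o in mol.bonds]:
            j, k = jk
            for i in sorted(adj[j] - {k}):
                for l in sorted(adj[k] - {j}):
                    if i == l:
                        continue
                    torsions.append((i, j, k, l))
                    if order in ("2", "ar", "am"):
                        tor_params.append((5.0, 2, -1.0))  # planar: V/2 (1 - cos 2phi)
                    elif order == "1":
                        tor_params.append((0.3, 3, 1.0))  # staggered: V/2 (1 + cos 3phi)
                    else:
                        tor_params.append((0.0, 1, 1.0))
        self.tor_idx = np.array(torsions, dtype=int).reshape(-1, 4)
        self.tor_v = np.array([p[0] for p in tor_params])
        self.tor_n = np.array([p[1] for p in tor_params])
        self.tor_s = np.array([p[2] for p in tor_params])

    def _angles(self, coords: np.ndarray) -> np.ndarray:
        i, j, k = self.angle_idx[:, 0], self.angle_idx[:, 1], self.angle_idx[:, 2]
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    def _dihedrals(self, coords: np.ndarray) -> np.ndarray:
        p0 = coords[self.tor_idx[:, 0]]
        p1 = coords[self.tor_idx[:, 1]]
        p2 = coords[self.tor_idx[:, 2]]
        p3 = coords[self.tor_idx[:, 3]]
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.maximum(np.linalg.norm(b2, axis=1), 1e-12)[:, None])
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(m1 * n2, axis=1)
        return np.arctan2(y, x)

    def vdw_energy(self, coords: np.ndarray) -> float:
        if not len(self.pair_idx):
            return 0.0
        d = np.linalg.norm(coords[self.pair_idx[:, 0]] - coords[self.pair_idx[:, 1]], axis=1)
        d = np.maximum(d, 1e-3)
        ratio = self.pair_r0 / d
        e = self.pair_eps * (ratio**12 - 2.0 * ratio**6)
        return float(np.sum(e))

    def torsion_energy(self, coords: np.ndarray) -> float:
        if not len(self.tor_idx):
            return 0.0
        phi = self._dihedrals(coords)
        e = 0.5 * self.tor_v * (1.0 + self.tor_s * np.cos(self.tor_n * phi))
        return float(np.sum(e))

    def total_batch(self, coords_batch: np.ndarray) -> np.ndarray:
        """total_no_elec for a (B, n_atoms, 3) batch of geometries."""
        cb = np.asarray(coords_batch, dtype=float)
        e = np.zeros(cb.shape[0])
        if len(self.pair_idx):
            d = np.linalg.norm(cb[:, self.pair_idx[:, 0]] - cb[:, self.pair_idx[:, 1]], axis=2)
            d = np.maximum(d, 1e-3)
            ratio = self.pair_r0 / d
            e += np.sum(self.pair_eps * (ratio**12 - 2.0 * ratio**6), axis=1)
        if len(self.tor_idx):
            p0 = cb[:, self.tor_idx[:, 0]]
            p1 = cb[:, self.tor_idx[:, 1]]
            p2 = cb[:, self.tor_idx[:, 2]]
            p3 = cb[:, self.tor_idx[:, 3]]
            b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            m1 = np.cross(n1, b2 / np.maximum(np.linalg.norm(b2, axis=2), 1e-12)[..., None])
            phi = np.arctan2(np.sum(m1 * n2, axis=2), np.sum(n1 * n2, axis=2))
            e += np.sum(0.5 * self.tor_v * (1.0 + self.tor_s * np.cos(self.tor_n * phi)), axis=1)
        if len(self.bond_idx):
            r = np.linalg.norm(cb[:, self.bond_idx[:, 0]] - cb[:, self.bond_idx[:, 1]], axis=2)
            e += np.sum(_K_BOND * (r - self.bond_r0) ** 2, axis=1)
        if len(self.angle_idx):
            i, j, k = self.angle_idx[:, 0], self.angle_idx[:, 1], self.angle_idx[:, 2]
            v1 = cb[:, i] - cb[:, j]
            v2 = cb[:, k] - cb[:, j]
            cosang = np.sum(v1 * v2, axis=2) / (
                np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2)
            )
            t = np.arccos(np.clip(cosang, -1.0, 1.0))
            e += np.sum(_K_ANGLE * (t - self.angle_t0) ** 2, axis=1)
        return e

    def bonded_energy(self, coords: np.ndarray) -> float:
        e = 0.0
        if len(self.bond_idx):
            r = np.linalg.norm(coords[self.bond_idx[:, 0]] - coords[self.bond_idx[:, 1]], axis=1)
            e += float(np.sum(_K_BOND * (r - self.bond_r0) ** 2))
        if len(self.angle_idx):
            t = self._angles(coords)
            e += float(np.sum(_K_ANGLE * (t - self.angle_t0) ** 2))
        return e


class TriposLikeBackend(EnergyModel):
    name = "tripos"

    def __init__(self) -> None:
        self._cache: dict[int, _TriposContext] = {}

    def _ctx(self, mol: MoleculeRecord) -> _TriposContext:
        ctx = self._cache.get(id(mol))
        if ctx is None or ctx.record is not mol:
            ctx = _TriposContext(mol)
            self._cache[id(mol)] = ctx
        return ctx

    def evaluate_terms(
        self, mol: MoleculeRecord, conf: Conformation | np.ndarray
    ) -> EnergyBreakdown:
        ctx = self._ctx(mol)
        coords = conf.coords if isinstance(conf, Conformation) else conf
        coords = np.asarray(coords, dtype=float)
        vdw = _cap(ctx.vdw_energy(coords))
        torsion = _cap(ctx.torsion_energy(coords))
        total = _cap(vdw + torsion + ctx.bonded_energy(coords))
        return EnergyBreakdown(vdw=vdw, torsion=torsion, total_no_elec=total)

    def total_no_elec(self, mol: MoleculeRecord, coords: np.ndarray) -> float:
        ctx = self._ctx(mol)
        coords = np.asarray(coords, dtype=float)
        return ctx.vdw_energy(coords) + ctx.torsion_energy(coords) + ctx.bonded_energy(coords)

    def gradient(self, mol: MoleculeRecord, coords: np.ndarray) -> np.ndarray:
        # batched central differences (all 6N displaced geometries at once)
        ctx = self._ctx(mol)
        x = np.asarray(coords, dtype=float)
        n3 = x.size
        h = 1e-5
        batch = np.broadcast_to(x.ravel(), (2 * n3, n3)).copy()
        batch[np.arange(n3), np.arange(n3)] += h
        batch[n3 + np.arange(n3), np.arange(n3)] -= h
        energies = ctx.total_batch(batch.reshape(2 * n3, -1, 3))
        return ((energies[:n3] - energies[n3:]) / (2 * h)).reshape(-1, 3)


_BACKENDS = {"mmff94": MMFF94Backend, "tripos": TriposLikeBackend, "tripos-like": TriposLikeBackend}
_backend_singletons: dict[str, EnergyModel] = {}


def get_backend(name: str) -> EnergyModel:
    key = name.lower()
    if key not in _BACKENDS:
        raise ValueError(f"unknown energy backend {name!r}; options: mmff94, tripos")
    if key not in _backend_singletons:
        _backend_singletons[key] = _BACKENDS[key]()
    return _backend_singletons[key]


def minimize_conformation(
    mol: MoleculeRecord,
    conf: Conformation,
    model: EnergyModel,
    max_steps: int = 100,
    grad_tol: float = 0.01,
) -> Conformation:
    """Conjugate-gradient refinement of total_no_elec (electrostatics excluded).

    Terminates at ``grad_tol`` on the gradient max-norm or after ``max_steps``
    iterations, whichever comes first. Never returns a higher-energy geometry
    than the input.
    """
    x0 = np.asarray(conf.coords, dtype=float)
    e0 = model.total_no_elec(mol, x0)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at minimization input")
    g0 = model.gradient(mol, x0)
    if np.max(np.abs(g0)) <= grad_tol:
        out = conf.copy()
        out.minimized = True
        out.source_ff = model.name
        out.min_steps = 0
        return out

    shape = x0.shape

    def fun(x_flat: np.ndarray) -> float:
        return model.total_no_elec(mol, x_flat.reshape(shape))

    def jac(x_flat: np.ndarray) -> np.ndarray:
        return model.gradient(mol, x_flat.reshape(shape)).ravel()

    res = _scipy_minimize(
        fun,
        x0.ravel(),
        jac=jac,
        method="CG",
        options={"maxiter": max_steps, "gtol": grad_tol, "norm": np.inf},
    )
    x_final = res.x.reshape(shape)
    e_final = model.total_no_elec(mol, x_final)
    if not np.isfinite(e_final) or e_final > e0:
        x_final, e_final = x0, e0
    out = Conformation(coords=x_final, minimized=True, source_ff=model.name)
    out.min_steps = int(res.nit)
    return out
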