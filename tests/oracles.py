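"""Independent oracles used to freeze expected values in the tests.

These deliberately avoid the package's own implementation paths: RMSD via the
quaternion eigenvalue method, chain placement via explicit z-matrix
trigonometry, and epsilon-Pareto filtering via exhaustive comparison.
"""

from __future__ import annotations

import itertools

import numpy as np


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between paired point sets via the quaternion (Horn /
    Kearsley) eigenvalue method."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    ga = np.sum(a * a)
    gb = np.sum(b * b)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    msd = max(0.0, (ga + gb - 2.0 * lam) / n)
    return float(np.sqrt(msd))


def zmatrix_chain(bond_lengths, bond_angles_deg, dihedrals_deg) -> np.ndarray:
    """Place a chain of atoms from internal coordinates (NeRF-style).

    bond_lengths[i] connects atom i+1 to atom i; bond_angles_deg[i] is the
    angle at atom i+1 between atoms (i, i+1, i+2); dihedrals_deg[i] is the
    dihedral of atoms (i, i+1, i+2, i+3).
    """
    n = len(bond_lengths) + 1
    coords = np.zeros((n, 3))
    coords[1] = [bond_lengths[0], 0.0, 0.0]
    if n > 2:
        theta = np.radians(bond_angles_deg[0])
        coords[2] = coords[1] + bond_lengths[1] * np.array(
            [-np.cos(theta), np.sin(theta), 0.0]
        )
    for i in range(3, n):
        r = bond_lengths[i - 1]
        theta = np.radians(bond_angles_deg[i - 2])
        phi = np.radians(dihedrals_deg[i - 3])
        b = coords[i - 1] - coords[i - 2]
        b_hat = b / np.linalg.norm(b)
        prev = coords[i - 2] - coords[i - 3]
        n_vec = np.cross(prev, b_hat)
        n_hat = n_vec / np.linalg.norm(n_vec)
        m_hat = np.cross(n_hat, b_hat)
        d_local = np.array(
            [
                -r * np.cos(theta),
                r * np.sin(theta) * np.cos(phi),
                r * np.sin(theta) * np.sin(phi),
            ]
        )
        coords[i] = coords[i - 1] + (
            d_local[0] * b_hat + d_local[1] * m_hat + d_local[2] * n_hat
        )
    return coords


def _box(vec: np.ndarray, eps: np.ndarray) -> tuple[int, ...]:
    return tuple(int(x) for x in np.floor(np.asarray(vec) / eps))


def _dominates(a, b) -> bool:
    a = np.asarray(a)
    b = np.asarray(b)
    return bool(np.all(a <= b) and np.any(a < b))


def brute_force_eps_boxes(points: np.ndarray, eps: np.ndarray) -> set[tuple[int, ...]]:
    """Epsilon-non-dominated box set of a point cloud (minimization form) by
    exhaustive pairwise box comparison."""
    boxes = {_box(p, eps) for p in points}
    return {
        b
        for b in boxes
        if not any(_dominates(np.array(o), np.array(b)) for o in boxes if o != b)
    }


def brute_force_pareto(points: np.ndarray) -> np.ndarray:
    """Indices of the Pareto-non-dominated points (minimization form)."""
    pts = np.asarray(points, dtype=float)
    keep = []
    for i, p in enumerate(pts):
        if not any(_dominates(q, p) for j, q in enumerate(pts) if j != i):
            keep.append(i)
    return np.array(keep, dtype=int)


def exhaustive_heavy_mappings(elements, bonds, heavy):
    """All element/adjacency-preserving permutations of the heavy atoms, by
    brute-force enumeration (for small fixtures only)."""
    heavy = list(heavy)
    adj = {
        frozenset((i, j))
        for i, j, *_ in bonds
        if i in heavy and j in heavy
    }
    mappings = []
    for perm in itertools.permutations(heavy):
        m = dict(zip(heavy, perm))
        if any(elements[i] != elements[m[i]] for i in heavy):
            continue
        if all(frozenset((m[i], m[j])) in adj for e in adj for i, j in [tuple(e)]):
            mappings.append(m)
    return mappings
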