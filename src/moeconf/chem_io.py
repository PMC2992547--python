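"""Tripos mol2 reading/writing and element-composition filtering.

The parser is deliberately tolerant: PDB-derived mol2 files are heterogeneous,
so element identity is keyed off the SYBYL atom-type prefix with a fallback to
the atom name. Charges are read when present but never required downstream
(electrostatics is excluded everywhere in this package).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MoleculeRecord",
    "Mol2ParseError",
    "ALLOWED_ELEMENTS",
    "read_mol2",
    "write_mol2",
    "filter_allowed_elements",
]

#: Element filter used for the validation set: organic elements only.
ALLOWED_ELEMENTS = frozenset({"C", "O", "N", "S", "F", "Cl", "Br", "P", "H"})

# Recognised element symbols, two-letter symbols first so "Cl" wins over "C".
_ELEMENTS_2 = (
    "Cl Br Si Se Li Na Mg Al Ca Fe Zn Cu Mn Co Ni As Mo Sn Sb Te Ba Pt Au Hg Pb Bi".split()
)
_ELEMENTS_1 = list("HCNOSPFBIK")


class Mol2ParseError(ValueError):
    """Raised when a @<TRIPOS>MOLECULE block cannot be parsed."""


@dataclass
class MoleculeRecord:
    """A molecular graph plus one reference 3D geometry.

    Bond lengths and angles of the reference geometry are treated as fixed by
    all torsion-space operations downstream.
    """

    name: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    bonds: list[tuple[int, int, str]]  # 0-based indices, mol2 bond-type string
    charges: np.ndarray | None = None
    atom_names: list[str] = field(default_factory=list)
    atom_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError("molecule must contain at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i}, {j}) references atoms out of range")
        if not self.atom_names:
            self.atom_names = [f"{el}{k + 1}" for k, el in enumerate(self.elements)]
        if not self.atom_types:
            self.atom_types = list(self.elements)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_atom_indices(self) -> list[int]:
        """Indices of all non-hydrogen atoms, in atom order."""
        return [i for i, el in enumerate(self.elements) if el != "H"]


def _element_from_token(token: str) -> str:
    """Element symbol from a SYBYL atom type or an atom name."""
    head = token.split(".", 1)[0]
    head = re.sub(r"[^A-Za-z].*$", "", head)
    cand = head[:2].capitalize()
    if cand in _ELEMENTS_2:
        return cand
    cand1 = head[:1].upper()
    if cand1 in _ELEMENTS_1:
        return cand1
    if head:
        return head.capitalize()
    raise ValueError(f"cannot derive an element from {token!r}")


def _parse_block(block: str, index: int) -> MoleculeRecord:
    lines = block.splitlines()
    # section name -> list of lines
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("@<TRIPOS>"):
            current = sections.setdefault(stripped[len("@<TRIPOS>"):].upper(), [])
            continue
        if current is not None and stripped and not stripped.startswith("#"):
            current.append(stripped)

    mol_lines = sections.get("MOLECULE", [])
    if not mol_lines:
        raise Mol2ParseError(f"molecule block {index}: missing MOLECULE section")
    name = mol_lines[0].strip() or f"mol{index}"

    atom_lines = sections.get("ATOM", [])
    if not atom_lines:
        raise Mol2ParseError(f"molecule block {index} ({name}): missing ATOM section")

    elements: list[str] = []
    names: list[str] = []
    types: list[str] = []
    xyz: list[list[float]] = []
    charges: list[float] = []
    have_charges = True
    id_to_pos: dict[int, int] = {}
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 6:
            raise Mol2ParseError(
                f"molecule block {index} ({name}): malformed ATOM line {ln!r}"
            )
        try:
            atom_id = int(parts[0])
            x, y, z = (float(p) for p in parts[2:5])
        except ValueError as exc:
            raise Mol2ParseError(
                f"molecule block {index} ({name}): malformed ATOM line {ln!r}"
            ) from exc
        atype = parts[5]
        try:
            el = _element_from_token(atype)
        except ValueError:
            el = _element_from_token(parts[1])
        id_to_pos[atom_id] = len(elements)
        elements.append(el)
        names.append(parts[1])
        types.append(atype)
        xyz.append([x, y, z])
        if len(parts) >= 9:
            try:
                charges.append(float(parts[8]))
            except ValueError:
                have_charges = False
        else:
            have_charges = False

    bonds: list[tuple[int, int, str]] = []
    for ln in sections.get("BOND", []):
        parts = ln.split()
        if len(parts) < 4:
            raise Mol2ParseError(
                f"molecule block {index} ({name}): malformed BOND line {ln!r}"
            )
        try:
            i, j = id_to_pos[int(parts[1])], id_to_pos[int(parts[2])]
        except (ValueError, KeyError) as exc:
            raise Mol2ParseError(
                f"molecule block {index} ({name}): bond references unknown atom in {ln!r}"
            ) from exc
        bonds.append((i, j, parts[3]))

    return MoleculeRecord(
        name=name,
        elements=elements,
        coords=np.array(xyz, dtype=float),
        bonds=bonds,
        charges=np.array(charges) if have_charges else None,
        atom_names=names,
        atom_types=types,
    )


def read_mol2(path: str | Path) -> list[MoleculeRecord]:
    """Parse a (possibly multi-molecule) Tripos mol2 file.

    Returns one :class:`MoleculeRecord` per ``@<TRIPOS>MOLECULE`` block, in
    file order.
    """
    text = Path(path).read_text()
    marker = "@<TRIPOS>MOLECULE"
    if marker not in text:
        raise Mol2ParseError(f"{path}: no @<TRIPOS>MOLECULE block found")
    chunks = text.split(marker)[1:]
    records = []
    for idx, chunk in enumerate(chunks):
        records.append(_parse_block(marker + chunk, idx))
    return records


_BOND_TYPES = {"1", "2", "3", "ar", "am", "du", "un", "nc"}


def write_mol2(records: Sequence[MoleculeRecord] | MoleculeRecord, path: str | Path) -> None:
    """Serialise records as a concatenated multi-molecule mol2 file."""
    if isinstance(records, MoleculeRecord):
        records = [records]
    if len(records) == 0:
        raise ValueError("cannot write an empty record list")
    out = []
    for rec in records:
        out.append("@<TRIPOS>MOLECULE")
        out.append(rec.name)
        out.append(f"{rec.n_atoms:>5d} {len(rec.bonds):>5d}     0     0     0")
        out.append("SMALL")
        out.append("NO_CHARGES" if rec.charges is None else "USER_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for i in range(rec.n_atoms):
            x, y, z = rec.coords[i]
            q = 0.0 if rec.charges is None else rec.charges[i]
            out.append(
                f"{i + 1:>7d} {rec.atom_names[i]:<8s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                f"{rec.atom_types[i]:<6s} 1 MOL {q:>8.4f}"
            )
        out.append("@<TRIPOS>BOND")
        for b, (i, j, order) in enumerate(rec.bonds):
            if order not in _BOND_TYPES:
                order = "1"
            out.append(f"{b + 1:>6d} {i + 1:>5d} {j + 1:>5d} {order:>4s}")
        out.append("")
    Path(path).write_text("\n".join(out))


def filter_allowed_elements(
    records: Iterable[MoleculeRecord],
    allowed: frozenset[str] | set[str] = ALLOWED_ELEMENTS,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Partition records into (kept, removed) by element composition.

    A record is kept iff every atom's element is in ``allowed``.
    """
    kept: list[MoleculeRecord] = []
    removed: list[MoleculeRecord] = []
    for rec in records:
        (kept if all(el in allowed for el in rec.elements) else removed).append(rec)
    return kept, removed
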