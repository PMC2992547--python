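"""FFBM / MECBM conformer generation for a single molecule.

FFBM optimizes {VDW, torsion energy} (both minimized); MECBM adds
{geometric dissimilarity to the input, radius of gyration} (both maximized,
which produces the extended-geometry bias of the multi-criteria mode).
After the evolutionary run the archive is energy-window filtered,
deduplicated by best-fit RMSD, capped, and optionally post-minimized under
the same or a different force field (mixed-force-field strategy).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chem_io import MoleculeRecord
from .emoea_core import Objective, ObjectiveSpec, run_emoea
from .energy_backends import EnergyModel, get_backend, minimize_conformation
from .torsion_geometry import (
    Conformation,
    ReferenceSuperposer,
    apply_torsions,
    best_fit_rmsd,
    measure_torsions,
    moving_index_arrays,
    perceive_rotatable_bonds,
    set_torsions,
)

__all__ = [
    "SamplerConfig",
    "Ensemble",
    "SamplerError",
    "build_objective_spec",
    "generate_ensemble",
    "energy_window_filter",
    "deduplicate",
    "DEFAULT_FFBM_EPSILONS",
    "DEFAULT_MECBM_EXTRA_EPSILONS",
]

DEFAULT_FFBM_EPSILONS = (5.0, 3.0)  # kcal/mol for (vdw, torsion)
DEFAULT_MECBM_EXTRA_EPSILONS = (0.4, 0.1)  # Angstrom for (GD, GR)


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    mode: str = "mecbm"  # "ffbm" | "mecbm"
    sampling_ff: str = "mmff94"
    minimize: bool = False
    minimization_ff: str | None = None  # defaults to sampling_ff
    epsilons: tuple[float, ...] | None = None
    n_pop: int = 200
    n_gen: int = 200
    max_conformers: int = 600
    energy_window: float = 20.0  # kcal/mol
    min_max_steps: int = 100
    min_grad_tol: float = 0.01  # kcal/mol/A
    dedup_rmsd: float = 0.2  # heavy-atom best-fit RMSD, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ffbm", "mecbm"):
            raise ValueError(f"unknown mode {self.mode!r}; expected 'ffbm' or 'mecbm'")
        if self.max_conformers < 1:
            raise ValueError("max_conformers must be >= 1")
        if not self.energy_window > 0:
            raise ValueError("energy_window must be positive")

    @property
    def effective_minimization_ff(self) -> str:
        return self.minimization_ff or self.sampling_ff

    @property
    def label(self) -> str:
        """Protocol label in M-F (or M-C-F for mixed minimization) style."""
        base = self.mode.upper()
        if self.minimize:
            base += "_MIN"
            if self.effective_minimization_ff != self.sampling_ff:
                return f"{base}-{self.sampling_ff}-{self.effective_minimization_ff}"
        return f"{base}-{self.sampling_ff}"


@dataclass
class Ensemble:
    molecule: MoleculeRecord
    conformers: list[Conformation]
    config: SamplerConfig
    wall_time_s: float = 0.0
    n_evaluations: int = 0

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def filter_energies(self) -> np.ndarray:
        return np.array([c.filter_energy for c in self.conformers])


def build_objective_spec(config: SamplerConfig) -> ObjectiveSpec:
    """FFBM: minimize (vdw, torsion). MECBM: plus maximize (GD, GR)."""
    if config.mode == "ffbm":
        eps = config.epsilons or DEFAULT_FFBM_EPSILONS
        if len(eps) != 2:
            raise ValueError("ffbm takes 2 epsilons")
        return ObjectiveSpec(
            (
                Objective("vdw", "minimize", eps[0]),
                Objective("torsion", "minimize", eps[1]),
            )
        )
    eps = config.epsilons or (DEFAULT_FFBM_EPSILONS + DEFAULT_MECBM_EXTRA_EPSILONS)
    if len(eps) != 4:
        raise ValueError("mecbm takes 4 epsilons")
    return ObjectiveSpec(
        (
            Objective("vdw", "minimize", eps[0]),
            Objective("torsion", "minimize", eps[1]),
            Objective("geometric_dissimilarity", "maximize", eps[2]),
            Objective("gyration_radius", "maximize", eps[3]),
        )
    )


def energy_window_filter(
    conformers: Sequence[Conformation], window: float = 20.0
) -> list[Conformation]:
    """Keep conformers within ``window`` of the set's lowest filter energy."""
    confs = list(conformers)
    if not confs:
        return []
    energies = np.array([c.filter_energy for c in confs])
    emin = float(energies.min())
    return [c for c, e in zip(confs, energies) if e <= emin + window]


def deduplicate(
    conformers: Sequence[Conformation],
    mol: MoleculeRecord,
    dedup_rmsd: float = 0.2,
) -> list[Conformation]:
    """Greedy energy-ordered scan; keeps a conformer iff its best-fit RMSD to
    every kept conformer is >= dedup_rmsd."""
    kept: list[Conformation] = []
    for c in conformers:
        if all(best_fit_rmsd(c, k, mol) >= dedup_rmsd for k in kept):
            kept.append(c)
    return kept


def _attach_energies(
    mol: MoleculeRecord, confs: Sequence[Conformation], model: EnergyModel
) -> None:
    for c in confs:
        if c.energy_terms is None or c.source_ff != model.name:
            c.energy_terms = model.evaluate_terms(mol, c)
            c.source_ff = model.name


def generate_ensemble(
    mol: MoleculeRecord,
    input_conf: Conformation,
    config: SamplerConfig,
) -> Ensemble:
    """Run the configured sampling protocol on one molecule."""
    t0 = time.monotonic()
    model = get_backend(config.sampling_ff)
    rotatable = perceive_rotatable_bonds(mol)
    spec = build_objective_spec(config)
    rng = np.random.default_rng(config.seed)

    if len(rotatable) == 0:
        conf = input_conf.copy()
        conf.energy_terms = model.evaluate_terms(mol, conf)
        conf.source_ff = model.name
        return Ensemble(
            molecule=mol,
            conformers=[conf],
            config=config,
            wall_time_s=time.monotonic() - t0,
            n_evaluations=1,
        )

    mecbm = config.mode == "mecbm"
    input_torsions = measure_torsions(mol, input_conf, rotatable)
    moving = moving_index_arrays(rotatable)
    heavy = np.asarray(mol.heavy_atom_indices, dtype=np.intp)
    gd_ref = ReferenceSuperposer(input_conf.coords, heavy) if mecbm else None
    base_coords = input_conf.coords

    def evaluator(genotype: np.ndarray) -> np.ndarray:
        coords = apply_torsions(base_coords, rotatable, input_torsions, genotype, moving)
        terms = model.evaluate_terms(mol, coords)
        if mecbm:
            gd = gd_ref.rmsd(coords)
            hx = coords[heavy]
            hx = hx - hx.mean(axis=0)
            gr = float(np.sqrt(np.mean(np.sum(hx * hx, axis=1))))
            return np.array([terms.vdw, terms.torsion, gd, gr])
        return np.array([terms.vdw, terms.torsion])
    archive = run_emoea(
        evaluator,
        spec,
        n_genes=len(rotatable),
        n_pop=config.n_pop,
        n_gen=config.n_gen,
        rng=rng,
        seeds=[input_torsions],
    )
    n_evals = config.n_pop * (1 + config.n_gen)

    # raw conformer stream = every individual the archive ever accepted
    # (deduplicated by genotype); the final archive alone would make the
    # max_conformers cap meaningless
    seen: set[bytes] = set()
    raw: list = []
    for ind in archive.accepted_log:
        key = ind.genotype.tobytes()
        if key not in seen:
            seen.add(key)
            raw.append(ind)

    conformers: list[Conformation] = []
    for ind in raw:
        conf = set_torsions(mol, input_conf, ind.genotype, rotatable)
        conf.objective_values = ind.objectives
        conf.energy_terms = model.evaluate_terms(mol, conf)
        conf.source_ff = model.name
        conformers.append(conf)
    conformers.sort(key=lambda c: c.filter_energy)

    conformers = energy_window_filter(conformers, config.energy_window)
    conformers = deduplicate(conformers, mol, config.dedup_rmsd)
    conformers = conformers[: config.max_conformers]

    if config.minimize:
        min_model = get_backend(config.effective_minimization_ff)
        refined = []
        for c in conformers:
            m = minimize_conformation(
                mol, c, min_model, config.min_max_steps, config.min_grad_tol
            )
            m.energy_terms = min_model.evaluate_terms(mol, m)
            refined.append(m)
        refined.sort(key=lambda c: c.filter_energy)
        refined = energy_window_filter(refined, config.energy_window)
        refined = deduplicate(refined, mol, config.dedup_rmsd)
        conformers = refined[: config.max_conformers]

    return Ensemble(
        molecule=mol,
        conformers=conformers,
        config=config,
        wall_time_s=time.monotonic() - t0,
        n_evaluations=n_evals,
    )
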