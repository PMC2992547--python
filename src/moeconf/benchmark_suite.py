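"""Benchmark machinery: best-fit RMSD records against reference ("bioactive")
conformations, cumulative recovery tables, ensemble-size/time summaries, and
per-molecule scaled heat maps of conformer energy and gyration radius."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_io import MoleculeRecord
from .conformer_sampler import Ensemble, energy_window_filter
from .torsion_geometry import Conformation, best_fit_rmsd, radius_of_gyration, superpose_rmsd

__all__ = [
    "BenchmarkRecord",
    "RecoveryTable",
    "HeatMapPanel",
    "DEFAULT_CUTOFFS",
    "best_fit_record",
    "recovery_table",
    "heatmap_panel",
    "summarize_protocols",
]

DEFAULT_CUTOFFS = (0.5, 1.0, 1.5, 2.0)


@dataclass
class BenchmarkRecord:
    molecule_id: str
    protocol: str
    best_rmsd: float | None  # None marks a per-molecule failure
    best_rmsd_identity: float | None = None  # without symmetry correction
    ensemble_size: int = 0
    wall_time_s: float = 0.0
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.best_rmsd is None


@dataclass
class RecoveryTable:
    cutoffs: tuple[float, ...]
    percentages: pd.DataFrame  # index = protocol, columns = cutoffs
    n_molecules: dict[str, int]


@dataclass
class HeatMapPanel:
    metric: str  # "energy" | "gyration_radius"
    scale: tuple[float, float]
    bin_edges: np.ndarray
    fractions: dict[str, np.ndarray]  # protocol -> per-bin fraction vector

    def to_json(self) -> str:
        return json.dumps(
            {
                "metric": self.metric,
                "scale": list(self.scale),
                "bin_edges": self.bin_edges.tolist(),
                "fractions": {k: v.tolist() for k, v in self.fractions.items()},
            }
        )


def best_fit_record(
    ensemble: Ensemble,
    bioactive: Conformation,
    protocol: str | None = None,
) -> BenchmarkRecord:
    """Minimum best-fit RMSD between any ensemble member and the reference."""
    mol = ensemble.molecule
    if bioactive.coords.shape != (mol.n_atoms, 3):
        return BenchmarkRecord(
            molecule_id=mol.name,
            protocol=protocol or ensemble.config.label,
            best_rmsd=None,
            error="topology mismatch between ensemble and reference",
        )
    if not ensemble.conformers:
        return BenchmarkRecord(
            molecule_id=mol.name,
            protocol=protocol or ensemble.config.label,
            best_rmsd=None,
            error="empty ensemble",
        )
    heavy_pairs = [(i, i) for i in mol.heavy_atom_indices]
    best = min(best_fit_rmsd(c, bioactive, mol) for c in ensemble.conformers)
    best_id = min(
        superpose_rmsd(c.coords, bioactive.coords, heavy_pairs) for c in ensemble.conformers
    )
    return BenchmarkRecord(
        molecule_id=mol.name,
        protocol=protocol or ensemble.config.label,
        best_rmsd=best,
        best_rmsd_identity=best_id,
        ensemble_size=len(ensemble),
        wall_time_s=ensemble.wall_time_s,
    )


def recovery_table(
    records: Sequence[BenchmarkRecord],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> RecoveryTable:
    """Cumulative percentage of molecules with best_rmsd <= cutoff, per
    protocol. Failed records count in the denominator and never recover."""
    recs = list(records)
    if not recs:
        raise ValueError("no benchmark records")
    by_protocol: dict[str, list[BenchmarkRecord]] = {}
    for r in recs:
        by_protocol.setdefault(r.protocol, []).append(r)
    rows = {}
    n_mol = {}
    for protocol, group in by_protocol.items():
        n = len(group)
        n_mol[protocol] = n
        rows[protocol] = [
            100.0 * sum(1 for r in group if not r.failed and r.best_rmsd <= c) / n
            for c in cutoffs
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"{c:g}" for c in cutoffs])
    return RecoveryTable(cutoffs=tuple(cutoffs), percentages=df, n_molecules=n_mol)


def _metric_values(
    ensemble: Ensemble, metric: str, window: float
) -> np.ndarray:
    confs = energy_window_filter(ensemble.conformers, window)
    if metric == "energy":
        return np.array([c.filter_energy for c in confs])
    if metric == "gyration_radius":
        return np.array([radius_of_gyration(c, ensemble.molecule) for c in confs])
    raise ValueError(f"unknown heat-map metric {metric!r}")


def heatmap_panel(
    ensembles: Mapping[str, Ensemble],
    metric: str,
    n_bins: int = 20,
    window: float = 20.0,
) -> HeatMapPanel:
    """Per-molecule heat-map rows over a scale shared across protocols.

    Bins are equal-width and half-open [lo, hi), with the final bin closed so
    values at the shared maximum land in the last bin. Each protocol row is a
    probability vector over the bins.
    """
    values = {p: _metric_values(e, metric, window) for p, e in ensembles.items()}
    nonempty = [v for v in values.values() if len(v)]
    if not nonempty:
        raise ValueError("no windowed conformers in any protocol")
    lo = float(min(v.min() for v in nonempty))
    hi = float(max(v.max() for v in nonempty))
    edges = np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / n_bins if hi > lo else 0.0
    fractions = {}
    for p, v in values.items():
        counts = np.zeros(n_bins)
        if len(v):
            if width == 0.0:
                idx = np.zeros(len(v), dtype=int)
            else:
                idx = np.clip(np.floor((v - lo) / width).astype(int), 0, n_bins - 1)
            np.add.at(counts, idx, 1.0)
            counts /= len(v)
        fractions[p] = counts
    return HeatMapPanel(metric=metric, scale=(lo, hi), bin_edges=edges, fractions=fractions)


def summarize_protocols(
    records: Sequence[BenchmarkRecord],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Per-protocol summary: recovery at each cutoff, mean ensemble size
    (rounded to the nearest conformer), mean wall time."""
    table = recovery_table(records, cutoffs)
    by_protocol: dict[str, list[BenchmarkRecord]] = {}
    for r in records:
        by_protocol.setdefault(r.protocol, []).append(r)
    rows = []
    for protocol, group in by_protocol.items():
        ok = [r for r in group if not r.failed]
        row = {"protocol": protocol}
        for c in cutoffs:
            row[f"recovery_{c:g}A_pct"] = table.percentages.loc[protocol, f"{c:g}"]
        row["mean_ensemble_size"] = (
            int(round(float(np.mean([r.ensemble_size for r in ok])))) if ok else 0
        )
        row["mean_time_s"] = float(np.mean([r.wall_time_s for r in ok])) if ok else float("nan")
        row["n_molecules"] = len(group)
        row["n_failed"] = len(group) - len(ok)
        rows.append(row)
    return pd.DataFrame(rows).set_index("protocol")
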