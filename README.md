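# moeconf

Multi-objective evolutionary conformer generation for small molecules in
torsion space, with benchmark machinery for measuring how well generated
ensembles recover reference ("bioactive") conformations.

Two sampling modes are provided:

- **FFBM** (force-field based mode): the ε-dominance multi-objective
  evolutionary algorithm (ε-MOEA) minimizes the van der Waals and torsion
  energy terms (ε = 5.0 and 3.0 kcal/mol).
- **MECBM** (multiple-empirical-criteria based mode): FFBM's objectives plus
  two maximized geometric objectives — dissimilarity to the input
  conformation (GD, ε = 0.4 Å) and the heavy-atom radius of gyration
  (GR, ε = 0.1 Å) — which bias the archive toward diverse, extended
  geometries.

Bond lengths and angles stay fixed at their input values; torsions on
acyclic single bonds are the only search variables. Population and
generation default to 200 each, ensembles are capped at 600 conformers,
filtered to a 20 kcal/mol energy window, and deduplicated at 0.2 Å
heavy-atom best-fit RMSD. Optional conjugate-gradient post-minimization
(≤100 steps, 0.01 kcal·mol⁻¹·Å⁻¹ gradient max-norm, electrostatics
excluded) can run under the sampling force field or a different one
(mixed-force-field strategy).

Energy backends: **mmff94** (MMFF94 terms via RDKit) and **tripos** (a
self-contained Lennard-Jones + cosine-torsion approximation with harmonic
bond/angle restraints, standing in for the Tripos force field).

## Layout

| module | role |
| --- | --- |
| `moeconf.chem_io` | Tripos mol2 read/write, organic-element filter |
| `moeconf.torsion_geometry` | rotatable-bond perception, torsion driving, Rg, GD, symmetry-aware best-fit RMSD |
| `moeconf.energy_backends` | backend-agnostic energy contract, MMFF94 + tripos-like, CG minimizer |
| `moeconf.emoea_core` | generic ε-dominance MOEA: dominance tests, box archive, variation, main loop |
| `moeconf.conformer_sampler` | FFBM/MECBM orchestration: objectives, window, dedup, cap, minimization |
| `moeconf.benchmark_suite` | best-fit RMSD records, cumulative recovery tables, scaled heat maps, protocol summaries |
| `moeconf.fixtures_and_cli` | seeded synthetic molecules with planted targets; `moeconf` CLI |

## CLI

```bash
# sample one molecule (mol2 in, multi-conformer mol2 out)
moeconf generate input.mol2 --mode mecbm --ff mmff94 --seed 1 --out ensemble.mol2

# run the benchmark protocol matrix on a reference set
moeconf benchmark --reference refs.mol2 --input inputs.mol2 --out-dir bench/
# ... or on a seeded synthetic fixture set
moeconf benchmark --fixtures 20 --pop 100 --gen 100 --seed 1 --out-dir bench/

# emit a synthetic benchmark set (input + planted reference mol2)
moeconf fixtures --n 20 --seed 1 --out-prefix set
```

`benchmark` writes `recovery.csv` (cumulative recovery at 0.5/1.0/1.5/2.0 Å),
`summary.csv` (recovery, mean ensemble size, mean wall time per protocol),
`heatmaps.json` (per-molecule energy and Rg bin fractions on a scale shared
across protocols) and `report.html`.

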