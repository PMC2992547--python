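"""Generic epsilon-dominance multi-objective evolutionary engine.

Steady-state scheme: each generation produces ``n_pop`` offspring one at a
time; every offspring is offered to both the epsilon-archive (box-level
dominance with same-box tie-breaking) and the working population (Pareto
replacement). All objectives are handled internally in minimization form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .torsion_geometry import wrap_angle

__all__ = [
    "Objective",
    "ObjectiveSpec",
    "Individual",
    "Archive",
    "VariationParams",
    "canonicalize",
    "pareto_dominates",
    "box_index",
    "archive_accept",
    "vary",
    "run_emoea",
]


@dataclass(frozen=True)
class Objective:
    name: str
    direction: str  # "minimize" | "maximize"
    epsilon: float

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


@dataclass(frozen=True)
class ObjectiveSpec:
    objectives: tuple[Objective, ...]

    def __post_init__(self) -> None:
        if len(self.objectives) < 2:
            raise ValueError("need at least 2 objectives")

    def __len__(self) -> int:
        return len(self.objectives)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([o.epsilon for o in self.objectives])

    @property
    def signs(self) -> np.ndarray:
        return np.array([1.0 if o.direction == "minimize" else -1.0 for o in self.objectives])


@dataclass
class Individual:
    genotype: np.ndarray
    objectives: np.ndarray  # raw, in each objective's natural direction
    canonical: np.ndarray  # minimization form
    phenotype: object | None = None


def canonicalize(objvec: Sequence[float] | np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
    """Sign-flip maximized objectives so that smaller is always better."""
    v = np.asarray(objvec, dtype=float)
    if v.shape != (len(spec),):
        raise ValueError(f"objective vector length {v.shape} != spec length {len(spec)}")
    return v * spec.signs


def pareto_dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff a <= b componentwise with at least one strict inequality."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return bool(np.all(a <= b) and np.any(a < b))


def box_index(canonical: np.ndarray, spec: ObjectiveSpec) -> tuple[int, ...]:
    """Per-objective floor(value / epsilon), the epsilon-box coordinates."""
    v = np.asarray(canonical, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite objective value")
    return tuple(int(x) for x in np.floor(v / spec.epsilons))


class Archive:
    """Set of mutually epsilon-non-dominated individuals, one per box.

    Members and their integer box coordinates are kept in parallel arrays so
    acceptance tests vectorize over the whole archive.
    """

    def __init__(self, spec: ObjectiveSpec):
        self.spec = spec
        self._members: list[Individual] = []
        self._box_rows: list[tuple[int, ...]] = []
        self._box_matrix = np.empty((0, len(spec)), dtype=np.int64)
        #: every individual ever inserted, in acceptance order (the raw
        #: conformer stream the sampler post-filters)
        self.accepted_log: list[Individual] = []

    @property
    def members(self) -> list[Individual]:
        return list(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def box_of(self, ind: Individual) -> tuple[int, ...]:
        return box_index(ind.canonical, self.spec)

    def occupied_boxes(self) -> set[tuple[int, ...]]:
        return set(self._box_rows)

    def _rebuild(self, keep: np.ndarray) -> None:
        self._members = [m for m, k in zip(self._members, keep) if k]
        self._box_rows = [b for b, k in zip(self._box_rows, keep) if k]
        self._box_matrix = self._box_matrix[keep]

    def _append(self, ind: Individual, box: tuple[int, ...]) -> None:
        self._members.append(ind)
        self._box_rows.append(box)
        self._box_matrix = np.vstack([self._box_matrix, np.array(box, dtype=np.int64)])

    def _replace(self, idx: int, ind: Individual) -> None:
        self._members[idx] = ind


def _corner_distance(ind: Individual, box: tuple[int, ...], spec: ObjectiveSpec) -> float:
    corner = np.array(box) * spec.epsilons
    return float(np.linalg.norm(ind.canonical - corner))


def archive_accept(archive: Archive, candidate: Individual) -> bool:
    """Offer a candidate to the archive; returns True if it was inserted.

    Box-level rules: reject if any member's box dominates the candidate's;
    evict members whose boxes the candidate's dominates; within the same box
    keep the Pareto-dominating individual, or on incomparability the one
    closer (Euclidean) to the box's lower corner.
    """
    spec = archive.spec
    cbox = box_index(candidate.canonical, spec)
    carr = np.array(cbox, dtype=np.int64)

    boxes = archive._box_matrix
    if len(boxes):
        le = boxes <= carr
        lt = boxes < carr
        if bool(np.any(np.all(le, axis=1) & np.any(lt, axis=1))):
            return False  # some member's box dominates the candidate's
        ge = boxes >= carr
        gt = boxes > carr
        dominated = np.all(ge, axis=1) & np.any(gt, axis=1)
        if bool(np.any(dominated)):
            archive._rebuild(~dominated)

    try:
        same_idx = archive._box_rows.index(cbox)
    except ValueError:
        archive._append(candidate, cbox)
        archive.accepted_log.append(candidate)
        return True
    incumbent = archive._members[same_idx]
    if pareto_dominates(candidate.canonical, incumbent.canonical):
        archive._replace(same_idx, candidate)
        archive.accepted_log.append(candidate)
        return True
    if pareto_dominates(incumbent.canonical, candidate.canonical):
        return False
    if _corner_distance(candidate, cbox, spec) < _corner_distance(incumbent, cbox, spec):
        archive._replace(same_idx, candidate)
        archive.accepted_log.append(candidate)
        return True
    return False


@dataclass(frozen=True)
class VariationParams:
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1 / n_genes


def _wrapped_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed shortest angular difference a - b in degrees."""
    return wrap_angle(np.asarray(a) - np.asarray(b))


def vary(
    parent1: np.ndarray,
    parent2: np.ndarray,
    rng: np.random.Generator,
    params: VariationParams = VariationParams(),
) -> np.ndarray:
    """Blend crossover along the shortest angular path plus uniform-reset
    per-gene mutation; child angles wrapped to [-180, 180)."""
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("parent length mismatch")
    child = p1.copy()
    n = len(child)
    if n == 0:
        return child
    if params.crossover_rate > 0 and rng.random() < params.crossover_rate:
        u = rng.random(n)
        child = p1 + u * _wrapped_diff(p2, p1)
    mut_rate = params.mutation_rate if params.mutation_rate is not None else 1.0 / n
    if mut_rate > 0:
        mask = rng.random(n) < mut_rate
        if np.any(mask):
            child[mask] = rng.uniform(-180.0, 180.0, size=int(mask.sum()))
    return wrap_angle(child)


def _dominates_fast(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def _tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    i, j = rng.integers(0, len(pop), size=2)
    a, b = pop[int(i)], pop[int(j)]
    if _dominates_fast(a.canonical, b.canonical):
        return a
    if _dominates_fast(b.canonical, a.canonical):
        return b
    return a if rng.random() < 0.5 else b


def run_emoea(
    evaluator: Callable[[np.ndarray], np.ndarray],
    spec: ObjectiveSpec,
    n_genes: int,
    n_pop: int = 200,
    n_gen: int = 200,
    rng: np.random.Generator | None = None,
    seeds: Sequence[np.ndarray] = (),
    variation: VariationParams = VariationParams(),
) -> Archive:
    """Run the steady-state epsilon-MOEA and return the final archive.

    Performs exactly ``n_pop`` initial + ``n_pop * n_gen`` offspring
    evaluations. ``seeds`` are genotypes injected into the initial
    population (e.g. the input conformation's measured torsions).
    """
    if rng is None:
        rng = np.random.default_rng()

    def make(genotype: np.ndarray) -> Individual:
        raw = np.asarray(evaluator(genotype), dtype=float)
        if raw.shape != (len(spec),):
            raise ValueError(
                f"evaluator returned {raw.shape}, expected ({len(spec)},)"
            )
        return Individual(
            genotype=np.asarray(genotype, dtype=float),
            objectives=raw,
            canonical=canonicalize(raw, spec),
        )

    init: list[np.ndarray] = [wrap_angle(np.asarray(s, dtype=float)) for s in seeds][:n_pop]
    while len(init) < n_pop:
        init.append(rng.uniform(-180.0, 180.0, size=n_genes))

    population: list[Individual] = []
    archive = Archive(spec)
    for g, genotype in enumerate(init):
        try:
            ind = make(genotype)
        except Exception as exc:
            raise RuntimeError(f"evaluator failed on initial individual {g}") from exc
        population.append(ind)
        archive_accept(archive, ind)

    pop_canon = np.stack([ind.canonical for ind in population])  # (n_pop, n_obj)
    for gen in range(n_gen):
        for step in range(n_pop):
            p1 = _tournament(population, rng)
            p2 = (
                archive._members[int(rng.integers(0, len(archive)))]
                if len(archive)
                else p1
            )
            child_geno = vary(p1.genotype, p2.genotype, rng, variation)
            try:
                child = make(child_geno)
            except Exception as exc:
                raise RuntimeError(
                    f"evaluator failed at generation {gen}, offspring {step}"
                ) from exc
            archive_accept(archive, child)
            # population update: replace a random dominated member, else a
            # random member if the child is non-dominated, else discard
            c = child.canonical
            le = pop_canon >= c
            lt = pop_canon > c
            dominated = np.flatnonzero(np.all(le, axis=1) & np.any(lt, axis=1))
            if len(dominated):
                idx = int(dominated[int(rng.integers(0, len(dominated)))])
            elif not bool(
                np.any(np.all(pop_canon <= c, axis=1) & np.any(pop_canon < c, axis=1))
            ):
                idx = int(rng.integers(0, n_pop))
            else:
                continue
            population[idx] = child
            pop_canon[idx] = c
    return archive
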