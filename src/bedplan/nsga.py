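"""Elitist non-dominated-sorting genetic algorithm for the integer plan model.

The solver keeps an integer-coded population of construction plans, evaluates
both objectives in minimisation convention, and iterates the classic
merge-sort-truncate loop: roulette selection on rank-reciprocal fitness,
uniform per-cell crossover, in-bounds resampling mutation, then elitist
truncation of the merged parent+offspring population by (rank, crowding
distance).  Constraints are handled by constrained domination — any feasible
plan dominates any infeasible one, and infeasible plans compare by total
violation — so no penalty weights are needed.

The run terminates at the generation cap or when the archive hypervolume
(reference point: component-wise worst of the first archive) stops improving
over a stagnation window.  Everything is driven by one
``numpy.random.Generator``, so a (problem, config, seed) triple reproduces
its archive exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import FEASIBILITY_TOL, PlanningProblem, evaluate_batch

__all__ = [
    "GAConfig",
    "ParetoArchive",
    "initialize_population",
    "dominates",
    "non_dominated_sort",
    "crowding_distance",
    "roulette_select",
    "crossover",
    "mutate",
    "round_repair",
    "hypervolume",
    "run",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the reference configuration (population 100, 500
    generations, Pareto fraction 0.8); operator rates and the stagnation
    rule are explicit because the reference relies on solver defaults.
    """

    population_size: int = 100
    generations: int = 500
    pareto_fraction: float = 0.8
    crossover_rate: float = 0.5
    mutation_rate: float = 0.1
    stagnation_window: int = 50
    stagnation_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.generations < 1:
            raise ValueError("generations must be positive")
        if not 0 < self.pareto_fraction <= 1:
            raise ValueError("pareto_fraction must lie in (0, 1]")
        if round(self.pareto_fraction * self.population_size) < 1:
            raise ValueError("pareto_fraction * population_size must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.stagnation_window < 1:
            raise ValueError("stagnation_window must be positive")
        if self.stagnation_tol < 0:
            raise ValueError("stagnation_tol must be non-negative")

    @property
    def archive_capacity(self) -> int:
        return int(round(self.pareto_fraction * self.population_size))


@dataclass
class ParetoArchive:
    """Mutually non-dominated solutions returned by the solver.

    ``objectives`` are stored in minimisation convention ``(-F1, F2)``;
    the ``economic_benefits`` / ``social_costs`` properties undo it.
    When no feasible plan was ever found, ``feasible`` is all-False and the
    archive holds the least-violating plans instead.
    """

    plans: np.ndarray          # (K, M, N) int
    objectives: np.ndarray     # (K, 2) minimisation convention
    feasible: np.ndarray       # (K,) bool
    generations_run: int = 0
    hv_history: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return self.plans.shape[0]

    @property
    def economic_benefits(self) -> np.ndarray:
        return -self.objectives[:, 0]

    @property
    def social_costs(self) -> np.ndarray:
        return self.objectives[:, 1]

    @property
    def all_infeasible(self) -> bool:
        return len(self) > 0 and not bool(self.feasible.any())


def initialize_population(
    problem: PlanningProblem, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniform integer population within per-cell bounds, shape (P, M, N)."""
    bounds = problem.bounds()
    return rng.integers(0, bounds + 1, size=(config.population_size, *bounds.shape), dtype=np.int64)


def dominates(obj_u, viol_u: float, obj_v, viol_v: float, tol: float = FEASIBILITY_TOL) -> bool:
    """Constrained Pareto domination of ``u`` over ``v``.

    Feasible beats infeasible; two infeasibles compare by total violation;
    two feasibles by standard dominance on the minimised objectives.
    """
    feas_u = viol_u <= tol
    feas_v = viol_v <= tol
    if feas_u and not feas_v:
        return True
    if feas_v and not feas_u:
        return False
    if not feas_u and not feas_v:
        return viol_u < viol_v
    u = np.asarray(obj_u, dtype=float)
    v = np.asarray(obj_v, dtype=float)
    return bool((u <= v).all() and (u < v).any())


def _domination_matrix(objectives: np.ndarray, violations: np.ndarray) -> np.ndarray:
    """Boolean matrix D with D[u, v] True iff u dominates v (constrained)."""
    feas = violations <= FEASIBILITY_TOL
    le = (objectives[:, None, :] <= objectives[None, :, :]).all(axis=2)
    lt = (objectives[:, None, :] < objectives[None, :, :]).any(axis=2)
    both_feas = feas[:, None] & feas[None, :]
    d = both_feas & le & lt
    d |= feas[:, None] & ~feas[None, :]
    d |= ~feas[:, None] & ~feas[None, :] & (violations[:, None] < violations[None, :])
    return d

def non_dominated_sort(objectives: np.ndarray, violations: np.ndarray | None = None) -> np.ndarray:
    """1-based Pareto ranks by iterative front peeling (agrees with the
    pairwise definition: rank r is non-dominated once ranks < r are removed)."""
    objectives = np.asarray(objectives, dtype=float)
    k = objectives.shape[0]
    if violations is None:
        violations = np.zeros(k)
    d = _domination_matrix(objectives, np.asarray(violations, dtype=float))
    ranks = np.zeros(k, dtype=np.int64)
    alive = np.ones(k, dtype=bool)
    r = 1
    while alive.any():
        dominated = (d & alive[:, None]).any(axis=0)
        front = alive & ~dominated
        if not front.any():  # pragma: no cover - impossible for a strict partial order
            front = alive
        ranks[front] = r
        alive &= ~front
        r += 1
    return ranks


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front.

    Extremes of each objective get +inf; interior points sum their
    range-normalised neighbour gaps.  An objective with zero range
    contributes nothing.
    """
    f = np.asarray(front_objectives, dtype=float)
    if f.ndim != 2 or f.shape[0] == 0:
        raise ValueError("front must be a non-empty (K, n_objectives) array")
    k, n_obj = f.shape
    if k <= 2:
        return np.full(k, np.inf)
    dist = np.zeros(k)
    for j in range(n_obj):
        order = np.argsort(f[:, j], kind="stable")
        lo, hi = f[order[0], j], f[order[-1], j]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        rng = hi - lo
        if rng > 0:
            gaps = (f[order[2:], j] - f[order[:-2], j]) / rng
            dist[order[1:-1]] += gaps
    return dist


def roulette_select(ranks: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Indices sampled with replacement, proportional to fitness ``1 / rank``."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("cannot select from an empty population")
    weights = 1.0 / ranks
    return rng.choice(ranks.size, size=n_draws, replace=True, p=weights / weights.sum())


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rng: np.random.Generator,
    rate: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform per-cell crossover: each cell swaps with probability ``rate``.

    Works element-wise, so stacked parents (batch leading dimensions) are
    crossed in one call.
    """
    a = np.asarray(parent_a)
    b = np.asarray(parent_b)
    swap = rng.random(a.shape) < rate
    return np.where(swap, b, a), np.where(swap, a, b)


def mutate(
    child: np.ndarray,
    bounds: np.ndarray,
    rng: np.random.Generator,
    rate: float = 0.1,
) -> np.ndarray:
    """Resample each cell uniformly within its bounds with probability ``rate``."""
    x = np.asarray(child)
    mask = rng.random(x.shape) < rate
    fresh = rng.integers(0, np.broadcast_to(bounds, x.shape) + 1, size=x.shape, dtype=np.int64)
    return np.where(mask, fresh, x)


def round_repair(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Integer repair for real-coded operators: round to nearest, clip to bounds."""
    return np.clip(np.rint(np.asarray(x, dtype=float)), 0, bounds).astype(np.int64)


def hypervolume(points: np.ndarray, reference: np.ndarray) -> float:
    """2-D hypervolume (minimisation) dominated by ``points`` up to ``reference``."""
    p = np.asarray(points, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if p.size == 0:
        return 0.0
    p = p[(p <= ref).all(axis=1)]
    if p.shape[0] == 0:
        return 0.0
    p = p[np.lexsort((p[:, 1], p[:, 0]))]
    hv = 0.0
    prev_f1 = ref[1]
    for f0, f1 in p:
        if f1 < prev_f1:
            hv += (ref[0] - f0) * (prev_f1 - f1)
            prev_f1 = f1
    return hv


def _truncation_order(
    genomes: np.ndarray, ranks: np.ndarray, crowd: np.ndarray
) -> np.ndarray:
    """Deterministic elitist order: rank asc, crowding desc, genome lex asc."""
    flat = genomes.reshape(genomes.shape[0], -1)
    keys = [flat[:, j] for j in range(flat.shape[1] - 1, -1, -1)]
    keys.append(-crowd)
    keys.append(ranks)
    return np.lexsort(tuple(keys))


def _crowding_by_front(objectives: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    crowd = np.zeros(ranks.shape[0])
    for r in np.unique(ranks):
        idx = np.flatnonzero(ranks == r)
        crowd[idx] = crowding_distance(objectives[idx])
    return crowd


def _extract_archive(
    genomes: np.ndarray,
    objectives: np.ndarray,
    violations: np.ndarray,
    ranks: np.ndarray,
    capacity: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique rank-1 genomes, capped at ``capacity`` by crowding then lex order."""
    idx = np.flatnonzero(ranks == 1)
    flat = genomes[idx].reshape(idx.size, -1)
    _, uniq = np.unique(flat, axis=0, return_index=True)
    idx = idx[np.sort(uniq)]
    if idx.size > capacity:
        crowd = crowding_distance(objectives[idx])
        order = _truncation_order(genomes[idx], np.ones(idx.size, dtype=np.int64), crowd)
        idx = idx[order[:capacity]]
    # sort archive members lexicographically for a reproducible presentation
    order = np.lexsort(tuple(genomes[idx].reshape(idx.size, -1)[:, ::-1].T))
    idx = idx[order]
    return genomes[idx], objectives[idx], violations[idx]


def run(problem: PlanningProblem, config: GAConfig) -> ParetoArchive:
    """Solve the bi-objective integer program; return the Pareto archive.

    The archive holds at most ``round(pareto_fraction * population_size)``
    distinct rank-1 plans (all of them if fewer).  If no feasible plan is
    found, the archive is returned with every ``feasible`` flag False so the
    caller can report infeasibility explicitly.
    """
    rng = np.random.default_rng(config.seed)
    bounds = problem.bounds()
    pop = initialize_population(problem, config, rng)
    obj, viol = evaluate_batch(pop, problem)

    reference: np.ndarray | None = None
    hv_history: list[float] = []
    generations_run = 0

    for gen in range(config.generations):
        ranks = non_dominated_sort(obj, viol)

        # archive bookkeeping for the stagnation test
        feas_front = (ranks == 1) & (viol <= FEASIBILITY_TOL)
        if reference is None and feas_front.any():
            reference = obj[feas_front].max(axis=0)
        hv_history.append(
            hypervolume(obj[feas_front], reference) if reference is not None else 0.0
        )
        if (
            len(hv_history) > config.stagnation_window
            and reference is not None
            and hv_history[-1] - hv_history[-1 - config.stagnation_window]
            < config.stagnation_tol
        ):
            break

        # breeding: roulette on rank-reciprocal fitness, pairwise crossover
        n_parents = config.population_size + (config.population_size % 2)
        parent_idx = roulette_select(ranks, n_parents, rng)
        a, b = pop[parent_idx[0::2]], pop[parent_idx[1::2]]
        child_a, child_b = crossover(a, b, rng, config.crossover_rate)
        children = np.concatenate([child_a, child_b], axis=0)[: config.population_size]
        children = mutate(children, bounds, rng, config.mutation_rate)

        # merge, re-rank, elitist truncation
        merged = np.concatenate([pop, children], axis=0)
        child_obj, child_viol = evaluate_batch(children, problem)
        merged_obj = np.concatenate([obj, child_obj], axis=0)
        merged_viol = np.concatenate([viol, child_viol], axis=0)
        merged_ranks = non_dominated_sort(merged_obj, merged_viol)
        crowd = _crowding_by_front(merged_obj, merged_ranks)
        order = _truncation_order(merged, merged_ranks, crowd)
        keep = order[: config.population_size]
        pop, obj, viol = merged[keep], merged_obj[keep], merged_viol[keep]
        generations_run = gen + 1

    ranks = non_dominated_sort(obj, viol)
    plans, objectives, violations = _extract_archive(
        pop, obj, viol, ranks, config.archive_capacity
    )
    return ParetoArchive(
        plans=plans,
        objectives=objectives,
        feasible=violations <= FEASIBILITY_TOL,
        generations_run=generations_run,
        hv_history=hv_history,
    )
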