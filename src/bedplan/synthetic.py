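"""Synthetic planning instances and the exhaustive Pareto oracle.

The generator emulates the structure of real graded-capacity problems —
coefficients decreasing from the highest grade to the lowest, non-negative
initial bed stocks, a bed-rate floor calibrated so the instance is solvable —
at sizes small enough that the solver can be checked against brute-force
enumeration of every integer plan in bounds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    DistrictState,
    GradeParameters,
    InfeasibleProblemError,
    PlanningProblem,
    evaluate_batch,
    FEASIBILITY_TOL,
)
from .nsga import ParetoArchive

__all__ = ["SyntheticSpec", "generate_problem", "brute_force_pareto"]

#: Enumeration cap: instances with more candidate plans than this are
#: rejected by the oracle to keep exhaustive checks desk-scale.
MAX_ENUMERATED_PLANS = 10**6


@dataclass(frozen=True)
class SyntheticSpec:
    """Ranges for one random planning instance.

    With ``grade_monotone`` (the realistic default) the cost, income, and
    bed coefficients strictly decrease from the highest grade to the lowest,
    and the benefit/cost ratios differ across grades so the Pareto front
    does not collapse to a line.
    """

    n_grades: int = 3
    n_cycles: int = 2
    cost_range: tuple[float, float] = (100.0, 12000.0)
    income_range: tuple[float, float] = (100.0, 8000.0)
    bed_range: tuple[float, float] = (10.0, 800.0)
    d0_range: tuple[int, int] = (0, 500)
    share: float = 0.15
    bound_cap: int = 4
    rate_fill: tuple[float, float] = (0.3, 0.9)
    grade_monotone: bool = True

    def __post_init__(self) -> None:
        if self.n_grades < 1 or self.n_cycles < 1:
            raise ValueError("n_grades and n_cycles must be positive")
        for name in ("cost_range", "income_range", "bed_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive and ordered")
        if not 0 <= self.share <= 1 or self.share * self.n_grades > 1:
            raise ValueError("share must be in [0, 1] with share * n_grades <= 1")
        if self.bound_cap < 0:
            raise ValueError("bound_cap must be non-negative")
        lo, hi = self.rate_fill
        if not 0 < lo <= hi <= 1:
            raise ValueError("rate_fill must satisfy 0 < lo <= hi <= 1")


def _draw_coefficients(rng: np.random.Generator, spec: SyntheticSpec, lo: float, hi: float) -> np.ndarray:
    vals = rng.uniform(lo, hi, size=spec.n_grades)
    if spec.grade_monotone:
        vals = np.sort(vals)[::-1]
        # enforce strict decrease even after a tied draw
        for k in range(1, spec.n_grades):
            if vals[k] >= vals[k - 1]:
                vals[k] = np.nextafter(vals[k - 1], 0.0)
    return vals


def generate_problem(spec: SyntheticSpec, seed: int, max_attempts: int = 100) -> PlanningProblem:
    """Draw a random horizon-mode instance that admits a feasible plan.

    Instances are rejection-sampled until the all-max plan (every cell at
    its upper bound) is feasible, so the solver and the oracle always have
    something to find.  Reproducible for a fixed (spec, seed).
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        cost = _draw_coefficients(rng, spec, *spec.cost_range)
        income = _draw_coefficients(rng, spec, *spec.income_range)
        beds = _draw_coefficients(rng, spec, *spec.bed_range)
        d0 = rng.integers(spec.d0_range[0], spec.d0_range[1] + 1, size=spec.n_grades)
        bounds = rng.integers(1, spec.bound_cap + 1, size=(spec.n_cycles, spec.n_grades))
        grades = GradeParameters(
            cost=cost,
            income=income,
            beds=beds,
            min_share=np.full(spec.n_grades, spec.share),
        )
        district = DistrictState(
            name=f"synthetic-{seed}",
            institution_counts=np.zeros(spec.n_grades, dtype=np.int64),
            initial_beds=d0,
        )
        all_max_beds = float(d0.sum() + (bounds * beds[None, :]).sum())
        population = 1000.0
        fill = rng.uniform(*spec.rate_fill)
        rate = fill * all_max_beds / population
        problem = PlanningProblem(
            district=district,
            grades=grades,
            n_cycles=spec.n_cycles,
            bed_rate_targets=np.array([rate]),
            horizon_population=population,
            upper_bounds=bounds,
        )
        _, viol = evaluate_batch(bounds[None, :, :].astype(float), problem)
        if viol[0] <= FEASIBILITY_TOL:
            return problem
    raise InfeasibleProblemError(
        f"no feasible instance found in {max_attempts} attempts for {spec!r}"
    )


def _pareto_mask(objectives: np.ndarray) -> np.ndarray:
    """Boolean mask of the exact non-dominated rows (2-D minimisation)."""
    obj = np.asarray(objectives, dtype=float)
    pairs, inverse = np.unique(obj, axis=0, return_inverse=True)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    keep_pair = np.zeros(pairs.shape[0], dtype=bool)
    best_f1 = np.inf
    i = 0
    while i < order.size:
        # group of equal f0, already sorted by f1 ascending
        j = i
        f0 = pairs[order[i], 0]
        while j < order.size and pairs[order[j], 0] == f0:
            j += 1
        if pairs[order[i], 1] < best_f1:
            keep_pair[order[i]] = True
            best_f1 = pairs[order[i], 1]
        i = j
    return keep_pair[inverse]


def brute_force_pareto(problem: PlanningProblem, max_plans: int = MAX_ENUMERATED_PLANS) -> ParetoArchive:
    """Exact Pareto archive by enumerating every integer plan in bounds.

    Enumerates the full box ``prod(upper_bound + 1)`` (rejected above
    ``max_plans``), keeps the feasible plans, and returns every plan whose
    objective pair is non-dominated.  Raises
    :class:`~bedplan.model.InfeasibleProblemError` if no plan is feasible.
    """
    bounds = problem.bounds()
    n_plans = int(np.prod(bounds.astype(object) + 1))
    if n_plans > max_plans:
        raise ValueError(
            f"instance has {n_plans} candidate plans, above the enumeration cap {max_plans}"
        )
    cells = [range(b + 1) for b in bounds.ravel()]
    plans = np.array(list(itertools.product(*cells)), dtype=np.int64).reshape(
        n_plans, *bounds.shape
    )
    obj, viol = evaluate_batch(plans, problem)
    feasible = viol <= FEASIBILITY_TOL
    if not feasible.any():
        raise InfeasibleProblemError("no feasible plan exists within the bounds")
    plans, obj = plans[feasible], obj[feasible]
    mask = _pareto_mask(obj)
    plans, obj = plans[mask], obj[mask]
    order = np.lexsort(tuple(plans.reshape(plans.shape[0], -1)[:, ::-1].T))
    return ParetoArchive(
        plans=plans[order],
        objectives=obj[order],
        feasible=np.ones(mask.sum(), dtype=bool),
    )
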