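"""Core planning model: problem data, objectives, and constraints.

The model plans the construction of elder-care institutions of ``N`` quality
grades (by default five, labelled AAAAA down to A) over ``M`` multi-year
construction cycles.  The decision variable is an ``M x N`` matrix of
non-negative integers ``x[i, j]``: how many institutions of grade ``j`` to
build in cycle ``i``.  Two linear objectives compete:

* economic benefit ``F1 = sum_ij factor_i * b_j * x_ij`` (maximised), where
  ``b_j`` is the per-institution income coefficient and ``factor_i`` an
  optional per-cycle multiplier (used by the smart-community scenario);
* social cost ``F2 = sum_ij a_j * x_ij`` (minimised), where ``a_j`` is the
  per-institution construction-cost coefficient.

Internally both objectives are stored in minimisation convention as
``(-F1, F2)``.

Constraints come in two modes, selected by the length of
``bed_rate_targets``:

* *horizon* mode (one target): total beds at the end of the horizon must
  reach ``rate * P_horizon`` (beds per capita times the projected elderly
  population), and each grade's final bed stock must hold at least a minimum
  share ``p_j`` of all beds;
* *per-cycle* mode (``M`` targets): cumulative beds through each cycle must
  reach that cycle's ``rate_i * P_ref`` floor, and the grade-share floors are
  enforced on cumulative beds at every cycle.

Bed stocks convert from institution counts through the bed coefficient
``c_j`` (average beds per institution of grade ``j``).  Initial bed stocks
are derived from existing institution counts with the *ceiling* of ``c_j``
(matching how the reference parameter table was tabulated), while constraint
arithmetic uses the raw ``c_j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "FEASIBILITY_TOL",
    "DEFAULT_GRADE_LABELS",
    "DimensionError",
    "InfeasibleProblemError",
    "GradeParameters",
    "DistrictState",
    "PlanningProblem",
    "PlanMatrix",
    "ObjectivePair",
    "FeasibilityReport",
    "derive_initial_beds",
    "economic_benefit",
    "social_cost",
    "horizon_bed_floor",
    "grade_share_floors",
    "cumulative_beds",
    "per_cycle_bed_floors",
    "per_cycle_share_floors",
    "evaluate",
    "evaluate_batch",
]

#: Slack below -FEASIBILITY_TOL counts as a violation; constraint arithmetic
#: is floating point, so exact zero cannot be required.
FEASIBILITY_TOL = 1e-9

#: Conventional grade labels, highest grade first (matches the order in
#: which the grade coefficient tables are printed).
DEFAULT_GRADE_LABELS = ("AAAAA", "AAAA", "AAA", "AA", "A")


class DimensionError(ValueError):
    """A plan's shape does not match the problem's cycles x grades."""


class InfeasibleProblemError(RuntimeError):
    """No feasible plan exists within the problem's bounds."""


def _as_1d_float(value, name: str, n: int | None = None) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
    return arr


@dataclass(frozen=True)
class GradeParameters:
    """Per-grade coefficients, ordered from the highest grade to the lowest.

    Parameters
    ----------
    cost
        Construction-cost coefficients ``a_j`` (area-like units per
        institution), >= 0.
    income
        Income coefficients ``b_j`` (currency-like units per institution),
        >= 0.
    beds
        Bed coefficients ``c_j`` (average beds per institution), > 0.
    min_share
        Minimum fraction ``p_j`` of total beds each grade must hold, each in
        [0, 1] and summing to at most 1 (otherwise no allocation can satisfy
        all the floors and the parameters are rejected).
    labels
        Grade names; defaults to AAAAA..A for five grades.
    """

    cost: np.ndarray
    income: np.ndarray
    beds: np.ndarray
    min_share: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        cost = _as_1d_float(self.cost, "cost")
        n = cost.shape[0]
        income = _as_1d_float(self.income, "income", n)
        beds = _as_1d_float(self.beds, "beds", n)
        min_share = _as_1d_float(self.min_share, "min_share", n)
        if n == 0:
            raise ValueError("at least one grade is required")
        if (cost < 0).any() or (income < 0).any():
            raise ValueError("cost and income coefficients must be non-negative")
        if (beds <= 0).any():
            raise ValueError("bed coefficients must be strictly positive")
        if ((min_share < 0) | (min_share > 1)).any():
            raise ValueError("minimum shares must lie in [0, 1]")
        if min_share.sum() > 1 + FEASIBILITY_TOL:
            raise ValueError(
                f"minimum grade shares sum to {min_share.sum():.6g} > 1; "
                "no bed allocation can satisfy them"
            )
        labels = self.labels
        if labels is None:
            labels = DEFAULT_GRADE_LABELS if n == 5 else tuple(f"G{k + 1}" for k in range(n))
        labels = tuple(str(s) for s in labels)
        if len(labels) != n:
            raise ValueError(f"labels has length {len(labels)}, expected {n}")
        for name, value in (
            ("cost", cost),
            ("income", income),
            ("beds", beds),
            ("min_share", min_share),
            ("labels", labels),
        ):
            object.__setattr__(self, name, value)

    @property
    def n_grades(self) -> int:
        return self.cost.shape[0]


def derive_initial_beds(institution_counts, bed_coeffs) -> np.ndarray:
    """Initial bed stock per grade from existing institution counts.

    Each grade contributes ``count_j * ceil(c_j)`` beds.  The ceiling
    reconciles fractional average bed coefficients with the integer bed
    stocks of the reference tabulation; constraint arithmetic elsewhere uses
    the raw coefficients.
    """
    counts = np.asarray(institution_counts)
    coeffs = np.asarray(bed_coeffs, dtype=float)
    if counts.ndim != 1 or coeffs.ndim != 1:
        raise ValueError("institution counts and bed coefficients must be vectors")
    if counts.shape[0] != coeffs.shape[0]:
        raise ValueError(
            f"length mismatch: {counts.shape[0]} counts vs {coeffs.shape[0]} coefficients"
        )
    if np.any(counts.astype(float) % 1 != 0) or (counts.astype(float) < 0).any():
        raise ValueError("institution counts must be non-negative integers")
    if (coeffs <= 0).any():
        raise ValueError("bed coefficients must be strictly positive")
    return (counts.astype(np.int64) * np.ceil(coeffs).astype(np.int64)).astype(np.int64)


@dataclass(frozen=True)
class DistrictState:
    """Existing institutions and beds of one district."""

    name: str
    institution_counts: np.ndarray
    initial_beds: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.institution_counts, dtype=np.int64)
        beds = np.asarray(self.initial_beds, dtype=np.int64)
        if counts.ndim != 1 or beds.ndim != 1 or counts.shape != beds.shape:
            raise ValueError("institution_counts and initial_beds must be equal-length vectors")
        if (counts < 0).any() or (beds < 0).any():
            raise ValueError("institution counts and initial beds must be non-negative")
        object.__setattr__(self, "institution_counts", counts)
        object.__setattr__(self, "initial_beds", beds)

    @classmethod
    def from_counts(cls, name: str, institution_counts, grades: GradeParameters) -> "DistrictState":
        """Build a district, deriving beds from counts with the ceiling rule."""
        beds = derive_initial_beds(institution_counts, grades.beds)
        return cls(name=name, institution_counts=np.asarray(institution_counts), initial_beds=beds)


@dataclass(frozen=True)
class PlanningProblem:
    """One district's planning instance.

    ``bed_rate_targets`` holds beds-per-capita fractions (e.g. 0.06 for 60
    beds per 1000 elderly).  Length 1 selects *horizon* mode (a single floor
    against ``horizon_population``); length ``n_cycles`` selects *per-cycle*
    mode (floors per cycle against ``reference_population``, a scalar or a
    per-cycle vector).

    ``income_factors`` multiplies the income coefficients per cycle (all 1.0
    for the baseline model; the smart-community scenario halves them from
    its switch cycle).

    ``upper_bounds`` caps each ``x[i, j]``; when omitted, a per-cell default
    is derived as ``ceil(max additional beds required / c_j)`` — the fewest
    institutions of grade ``j`` that could on their own close the largest
    bed-floor gap, so the all-max plan always has room to be feasible.
    """

    district: DistrictState
    grades: GradeParameters
    n_cycles: int
    bed_rate_targets: np.ndarray
    horizon_population: float | None = None
    reference_population: float | np.ndarray | None = None
    income_factors: np.ndarray | None = None
    upper_bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.grades.n_grades
        if self.district.initial_beds.shape[0] != n:
            raise ValueError("district grade vectors do not match the number of grades")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        rates = _as_1d_float(self.bed_rate_targets, "bed_rate_targets")
        if rates.shape[0] not in (1, self.n_cycles):
            raise ValueError(
                f"bed_rate_targets must have length 1 or {self.n_cycles}, got {rates.shape[0]}"
            )
        if (rates < 0).any():
            raise ValueError("bed-rate targets must be non-negative")
        object.__setattr__(self, "bed_rate_targets", rates)

        if rates.shape[0] == 1:
            if self.horizon_population is None:
                raise ValueError("horizon mode requires horizon_population")
        else:
            if self.reference_population is None:
                raise ValueError("per-cycle mode requires reference_population")
        if self.reference_population is not None:
            ref = np.asarray(self.reference_population, dtype=float)
            if ref.ndim == 1 and ref.shape[0] != self.n_cycles:
                raise ValueError("per-cycle reference_population must have one entry per cycle")
            if ref.ndim > 1:
                raise ValueError("reference_population must be a scalar or a per-cycle vector")
            object.__setattr__(self, "reference_population", ref)

        factors = self.income_factors
        if factors is None:
            factors = np.ones(self.n_cycles)
        factors = _as_1d_float(factors, "income_factors", self.n_cycles)
        if ((factors <= 0) | (factors > 1)).any():
            raise ValueError("income factors must lie in (0, 1]")
        object.__setattr__(self, "income_factors", factors)

        if self.upper_bounds is not None:
            ub = np.asarray(self.upper_bounds)
            if np.isscalar(self.upper_bounds) or ub.ndim == 0:
                ub = np.full((self.n_cycles, n), int(ub))
            ub = ub.astype(np.int64)
            if ub.shape != (self.n_cycles, n):
                raise ValueError(
                    f"upper_bounds must have shape ({self.n_cycles}, {n}), got {ub.shape}"
                )
            if (ub < 0).any():
                raise ValueError("upper bounds must be non-negative")
            object.__setattr__(self, "upper_bounds", ub)

    @property
    def n_grades(self) -> int:
        return self.grades.n_grades

    @property
    def mode(self) -> str:
        """``"horizon"`` or ``"per_cycle"``, per the number of rate targets."""
        return "horizon" if self.bed_rate_targets.shape[0] == 1 else "per_cycle"

    def required_new_beds(self) -> float:
        """Largest bed-floor requirement minus the initial bed stock (>= 0)."""
        d0_total = float(self.district.initial_beds.sum())
        if self.mode == "horizon":
            req = float(self.bed_rate_targets[0]) * float(self.horizon_population)
        else:
            req = float(np.max(self.bed_rate_targets * np.asarray(self.reference_population)))
        return max(req - d0_total, 0.0)

    def bounds(self) -> np.ndarray:
        """Per-cell upper bounds on the decision matrix (M x N integers)."""
        if self.upper_bounds is not None:
            return self.upper_bounds
        req = self.required_new_beds()
        per_grade = np.ceil(req / self.grades.beds).astype(np.int64)
        return np.tile(per_grade, (self.n_cycles, 1))

    def with_bounds(self, upper_bounds) -> "PlanningProblem":
        return replace(self, upper_bounds=upper_bounds)


@dataclass(frozen=True)
class PlanMatrix:
    """An M x N non-negative integer construction plan."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x)
        if x.ndim != 2:
            raise ValueError(f"plan must be a 2-D matrix, got shape {x.shape}")
        if np.any(np.asarray(x, dtype=float) % 1 != 0) or (x < 0).any():
            raise ValueError("plan entries must be non-negative integers")
        object.__setattr__(self, "x", x.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape


def _plan_array(plan, problem: PlanningProblem) -> np.ndarray:
    x = plan.x if isinstance(plan, PlanMatrix) else np.asarray(plan)
    if x.shape != (problem.n_cycles, problem.n_grades):
        raise DimensionError(
            f"plan shape {x.shape} does not match problem "
            f"({problem.n_cycles} cycles x {problem.n_grades} grades)"
        )
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class ObjectivePair:
    """Objectives in minimisation convention: ``(-F1, F2)``."""

    neg_benefit: float
    cost: float

    @property
    def economic_benefit(self) -> float:
        return -self.neg_benefit

    @property
    def social_cost(self) -> float:
        return self.cost

    def as_array(self) -> np.ndarray:
        return np.array([self.neg_benefit, self.cost])


@dataclass(frozen=True)
class FeasibilityReport:
    """Constraint slacks (>= 0 means satisfied) and their aggregate violation."""

    slacks: dict[str, np.ndarray]
    total_violation: float
    feasible: bool


def economic_benefit(plan, problem: PlanningProblem) -> float:
    """Economic benefit F1: income-weighted construction, per-cycle factored."""
    x = _plan_array(plan, problem)
    weights = problem.income_factors[:, None] * problem.grades.income[None, :]
    return float((x * weights).sum())


def social_cost(plan, problem: PlanningProblem) -> float:
    """Social cost F2: construction-cost-weighted total construction."""
    x = _plan_array(plan, problem)
    return float((x * problem.grades.cost[None, :]).sum())


def cumulative_beds(plan, problem: PlanningProblem, through_cycle: int) -> np.ndarray:
    """Bed stock per grade after ``through_cycle`` cycles of construction.

    ``through_cycle = 0`` returns the initial stock; cycle ``i`` adds
    ``c_j * x[i', j]`` for all cycles ``i' <= i`` (raw bed coefficients).
    """
    if not 0 <= through_cycle <= problem.n_cycles:
        raise ValueError(f"through_cycle must be in [0, {problem.n_cycles}], got {through_cycle}")
    x = _plan_array(plan, problem)
    d0 = problem.district.initial_beds.astype(float)
    if through_cycle == 0:
        return d0.copy()
    return d0 + (x[:through_cycle] * problem.grades.beds[None, :]).sum(axis=0)


def horizon_bed_floor(plan, problem: PlanningProblem) -> float:
    """Slack of the horizon bed floor: total final beds minus ``rate * P``."""
    if problem.mode != "horizon":
        raise ValueError("horizon_bed_floor applies to horizon-mode problems")
    total = cumulative_beds(plan, problem, problem.n_cycles).sum()
    return float(total - problem.bed_rate_targets[0] * problem.horizon_population)


def grade_share_floors(plan, problem: PlanningProblem) -> np.ndarray:
    """Slack per grade of the final-stock share floors.

    ``slack_k = final_beds_k - p_k * sum_j final_beds_j``, where final beds
    combine the initial stock with all planned construction.
    """
    final = cumulative_beds(plan, problem, problem.n_cycles)
    return final - problem.grades.min_share * final.sum()


def per_cycle_bed_floors(plan, problem: PlanningProblem) -> np.ndarray:
    """Slack per cycle of the cumulative bed floors (per-cycle mode)."""
    if problem.mode != "per_cycle":
        raise ValueError("per_cycle_bed_floors applies to per-cycle-mode problems")
    x = _plan_array(plan, problem)
    d0_total = float(problem.district.initial_beds.sum())
    new_per_cycle = (x * problem.grades.beds[None, :]).sum(axis=1)
    totals = d0_total + np.cumsum(new_per_cycle)
    ref = np.asarray(problem.reference_population, dtype=float)
    return totals - problem.bed_rate_targets * ref


def per_cycle_share_floors(plan, problem: PlanningProblem) -> np.ndarray:
    """M x N slacks of the grade-share floors applied to cumulative beds."""
    x = _plan_array(plan, problem)
    d0 = problem.district.initial_beds.astype(float)
    cum = d0[None, :] + np.cumsum(x * problem.grades.beds[None, :], axis=0)
    return cum - problem.grades.min_share[None, :] * cum.sum(axis=1, keepdims=True)


def evaluate_batch(plans: np.ndarray, problem: PlanningProblem) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised evaluation of a stack of plans.

    Parameters
    ----------
    plans
        Array of shape ``(K, M, N)``.

    Returns
    -------
    objectives : (K, 2) array
        ``(-F1, F2)`` per plan (minimisation convention).
    violations : (K,) array
        Sum of constraint-floor shortfalls; 0 for feasible plans.
    """
    x = np.asarray(plans, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (problem.n_cycles, problem.n_grades):
        raise DimensionError(
            f"expected shape (K, {problem.n_cycles}, {problem.n_grades}), got {x.shape}"
        )
    g = problem.grades
    f1 = (x * (problem.income_factors[:, None] * g.income[None, :])).sum(axis=(1, 2))
    f2 = (x * g.cost[None, :]).sum(axis=(1, 2))
    objectives = np.stack([-f1, f2], axis=1)

    d0 = problem.district.initial_beds.astype(float)
    cum = d0[None, None, :] + np.cumsum(x * g.beds[None, None, :], axis=1)  # (K, M, N)
    violation = np.zeros(x.shape[0])
    if problem.mode == "horizon":
        final = cum[:, -1, :]
        total = final.sum(axis=1)
        bed_slack = total - problem.bed_rate_targets[0] * problem.horizon_population
        share_slack = final - g.min_share[None, :] * total[:, None]
        violation += np.clip(-bed_slack, 0, None)
        violation += np.clip(-share_slack, 0, None).sum(axis=1)
    else:
        totals = cum.sum(axis=2)  # (K, M)
        ref = np.asarray(problem.reference_population, dtype=float)
        bed_slack = totals - problem.bed_rate_targets[None, :] * ref
        share_slack = cum - g.min_share[None, None, :] * totals[:, :, None]
        violation += np.clip(-bed_slack, 0, None).sum(axis=1)
        violation += np.clip(-share_slack, 0, None).sum(axis=(1, 2))
    return objectives, violation


def evaluate(plan, problem: PlanningProblem) -> tuple[ObjectivePair, FeasibilityReport]:
    """Evaluate one plan: objectives plus a named constraint-slack report."""
    x = _plan_array(plan, problem)
    objectives, _ = evaluate_batch(x[None, :, :], problem)
    pair = ObjectivePair(neg_benefit=float(objectives[0, 0]), cost=float(objectives[0, 1]))
    if problem.mode == "horizon":
        slacks = {
            "bed_floor": np.array([horizon_bed_floor(plan, problem)]),
            "grade_share": grade_share_floors(plan, problem),
        }
    else:
        slacks = {
            "cycle_bed_floor": per_cycle_bed_floors(plan, problem),
            "cycle_grade_share": per_cycle_share_floors(plan, problem),
        }
    total_violation = float(sum(np.clip(-s, 0, None).sum() for s in slacks.values()))
    report = FeasibilityReport(
        slacks=slacks,
        total_violation=total_violation,
        feasible=total_violation <= FEASIBILITY_TOL,
    )
    return pair, report
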