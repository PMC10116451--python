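"""Smart-community scenario: cheaper service income, faster bed targets.

The scenario models a planning horizon in which robotic/smart home care
scales up from a switch cycle onward: income coefficients are multiplied by
a factor (default 0.5 from cycle 3 — a 2+3 split of the five cycles), while
the beds-per-1000 policy targets escalate cycle by cycle instead of applying
only at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import PlanningProblem

__all__ = [
    "RateSchedule",
    "cycle_rate_targets",
    "build_smart_problem",
    "linear_rate_extrapolation",
]


@dataclass(frozen=True)
class RateSchedule:
    """Beds-per-1000 targets as a base rate plus per-cycle increments."""

    base_rate: float
    increments: tuple

    def __post_init__(self) -> None:
        inc = tuple(float(v) for v in self.increments)
        if any(v < 0 for v in inc):
            raise ValueError("per-cycle increments must be non-negative")
        object.__setattr__(self, "increments", inc)

    def targets(self) -> np.ndarray:
        return cycle_rate_targets(self.base_rate, self.increments)


def cycle_rate_targets(base_rate: float, increments) -> np.ndarray:
    """Cumulative per-cycle targets: ``rate_i = base + sum(increments[:i])``.

    Units are whatever the base rate uses — conventionally beds per 1000
    elderly, e.g. base 45 with increments (3, 3, 4, 4, 4) gives
    (48, 51, 55, 59, 63).
    """
    inc = np.asarray(increments, dtype=float)
    if inc.ndim != 1:
        raise ValueError("increments must be a vector")
    if (inc < 0).any():
        raise ValueError("per-cycle increments must be non-negative")
    return base_rate + np.cumsum(inc)


def build_smart_problem(
    base: PlanningProblem,
    switch_cycle: int = 3,
    income_factor: float = 0.5,
    schedule: RateSchedule | None = None,
    reference_population=None,
) -> PlanningProblem:
    """Derive the smart-community variant of a baseline problem.

    Income coefficients are multiplied by ``income_factor`` from
    ``switch_cycle`` (1-based) onward, and the single horizon bed floor is
    replaced by per-cycle floors from ``schedule`` (beds per 1000), checked
    against ``reference_population`` (defaults to the baseline horizon
    population).  Grade-share floors then apply to cumulative beds at every
    cycle.
    """
    m = base.n_cycles
    if not 1 <= switch_cycle <= m:
        raise ValueError(f"switch_cycle must lie in [1, {m}], got {switch_cycle}")
    if not 0 < income_factor <= 1:
        raise ValueError("income_factor must lie in (0, 1]")
    if schedule is None:
        raise ValueError("a RateSchedule is required")
    rates = schedule.targets() / 1000.0
    if rates.shape[0] != m:
        raise ValueError(f"schedule has {rates.shape[0]} cycles, problem has {m}")
    if reference_population is None:
        reference_population = base.horizon_population
    if reference_population is None:
        raise ValueError("a reference population is required")
    factors = np.ones(m)
    factors[switch_cycle - 1 :] = income_factor
    return replace(
        base,
        bed_rate_targets=rates,
        reference_population=np.asarray(reference_population, dtype=float),
        income_factors=factors,
    )


def linear_rate_extrapolation(
    rate_t0: float, rate_t1: float, year0: int, year1: int, target_year: int
) -> float:
    """Extrapolate a bed rate linearly from two observed years.

    E.g. 39 beds/1000 in 2018 and 45 in 2020 extrapolate to 90 by 2035.
    """
    if year1 == year0:
        raise ValueError("the two observation years must differ")
    slope = (rate_t1 - rate_t0) / (year1 - year0)
    return rate_t0 + (target_year - year0) * slope
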