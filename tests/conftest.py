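import numpy as np
import pytest

from bedplan.model import DistrictState, GradeParameters, PlanningProblem

# The published per-grade bed stocks (beds per district per grade, highest
# grade first) that the ceiling-rule derivation must reproduce from the
# institution census.
EXPECTED_INITIAL_BEDS = {
    "Xuanwu": (0, 532, 1352, 150, 0),
    "Qinhuai": (0, 1596, 1352, 525, 175),
    "Gulou": (0, 1862, 2535, 225, 175),
    "Liuhe": (0, 266, 507, 75, 35),
    "Jianye": (778, 532, 676, 0, 70),
    "Yuhuatai": (0, 532, 1690, 150, 140),
    "Qixia": (1556, 1064, 169, 675, 245),
    "Pukou": (778, 266, 507, 450, 35),
    "Jiangning": (1556, 1596, 1352, 150, 280),
    "Lishui": (0, 266, 676, 75, 35),
    "Gaochun": (0, 266, 0, 0, 0),
}

PRINTED_BED_COEFFS = (777.6, 265.4, 168.1428571, 74.33333333, 35.0)


@pytest.fixture
def make_problem():
    """Factory for small hand-specified horizon-mode problems."""

    def _make(
        *,
        a=None,
        b=None,
        c=(10.0,),
        d0=None,
        p=None,
        n_cycles=1,
        rate=0.0,
        population=1000.0,
        bounds=None,
        rates=None,
        reference_population=None,
        income_factors=None,
        name="test",
    ):
        n = len(c)
        a = (1.0,) * n if a is None else a
        b = (1.0,) * n if b is None else b
        d0 = (0,) * n if d0 is None else d0
        p = (0.0,) * n if p is None else p
        grades = GradeParameters(cost=a, income=b, beds=c, min_share=p)
        district = DistrictState(
            name=name,
            institution_counts=np.zeros(n, dtype=np.int64),
            initial_beds=np.asarray(d0, dtype=np.int64),
        )
        if rates is not None:
            return PlanningProblem(
                district=district,
                grades=grades,
                n_cycles=n_cycles,
                bed_rate_targets=np.asarray(rates, dtype=float),
                reference_population=reference_population,
                income_factors=income_factors,
                upper_bounds=bounds,
            )
        return PlanningProblem(
            district=district,
            grades=grades,
            n_cycles=n_cycles,
            bed_rate_targets=np.array([rate]),
            horizon_population=population,
            income_factors=income_factors,
            upper_bounds=bounds,
        )

    return _make


@pytest.fixture
def qinhuai():
    from bedplan.io import load_problem

    return load_problem("nanjing/Qinhuai")


@pytest.fixture
def xuanwu():
    from bedplan.io import load_problem

    return load_problem("nanjing/Xuanwu")
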