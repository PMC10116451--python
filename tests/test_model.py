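"""Objective and constraint arithmetic of the core planning model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from bedplan.io import load_problem, nanjing_districts
from bedplan.model import (
    DimensionError,
    GradeParameters,
    PlanMatrix,
    cumulative_beds,
    derive_initial_beds,
    economic_benefit,
    evaluate,
    evaluate_batch,
    grade_share_floors,
    horizon_bed_floor,
    per_cycle_bed_floors,
    per_cycle_share_floors,
    social_cost,
)
from conftest import EXPECTED_INITIAL_BEDS, PRINTED_BED_COEFFS


class TestDeriveInitialBeds:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((0, 6, 8, 7, 5), (0, 1596, 1352, 525, 175)),  # Qinhuai census row
            ((0, 0, 0, 0, 0), (0, 0, 0, 0, 0)),
            ((1, 1, 1, 1, 1), (778, 266, 169, 75, 35)),  # ceil of each coefficient
        ],
    )
    def test_examples(self, counts, expected):
        got = derive_initial_beds(counts, PRINTED_BED_COEFFS)
        assert got.tolist() == list(expected)

    def test_reproduces_published_bed_table(self):
        """Ceiling-rule derivation matches all 55 published per-grade stocks."""
        for district in nanjing_districts():
            problem = load_problem(f"nanjing/{district}")
            assert problem.district.initial_beds.tolist() == list(
                EXPECTED_INITIAL_BEDS[district]
            ), district

    @pytest.mark.parametrize(
        "counts, coeffs",
        [
            ((1, 2), (10.0,)),          # length mismatch
            ((-1, 2), (10.0, 5.0)),     # negative count
            ((1, 2), (10.0, 0.0)),      # non-positive coefficient
            ((1.5, 2.0), (10.0, 5.0)),  # fractional count
        ],
    )
    def test_rejects_bad_inputs(self, counts, coeffs):
        with pytest.raises(ValueError):
            derive_initial_beds(counts, coeffs)


class TestObjectives:
    def test_single_top_grade_institution_benefit(self, xuanwu):
        plan = np.zeros((5, 5), dtype=int)
        plan[0, 0] = 1  # one AAAAA institution in cycle 1
        assert economic_benefit(plan, xuanwu) == pytest.approx(7916)

    def test_zero_plan_objectives(self, xuanwu):
        zero = np.zeros((5, 5), dtype=int)
        assert economic_benefit(zero, xuanwu) == 0
        assert social_cost(zero, xuanwu) == 0

    def test_income_factor_halves_late_benefit(self, xuanwu):
        from bedplan.scenario import RateSchedule, build_smart_problem

        smart = build_smart_problem(
            xuanwu, schedule=RateSchedule(45, (3, 3, 4, 4, 4))
        )
        plan = np.zeros((5, 5), dtype=int)
        plan[2, 0] = 1  # one AAAAA institution in cycle 3, after the switch
        assert economic_benefit(plan, smart) == pytest.approx(0.5 * 7916)

    def test_single_mid_grade_cost(self, xuanwu):
        for cycle in range(5):
            plan = np.zeros((5, 5), dtype=int)
            plan[cycle, 2] = 1  # one AAA institution
            assert social_cost(plan, xuanwu) == pytest.approx(3600)

    def test_two_of_each_grade_cost(self, xuanwu):
        plan = np.zeros((5, 5), dtype=int)
        plan[1, :] = 2
        assert social_cost(plan, xuanwu) == pytest.approx(48600)

    def test_dimension_mismatch_rejected(self, xuanwu):
        with pytest.raises(DimensionError):
            economic_benefit(np.zeros((3, 5)), xuanwu)
        with pytest.raises(DimensionError):
            social_cost(np.zeros((5, 4)), xuanwu)


class TestBedFloors:
    def test_existing_stock_surplus(self, make_problem):
        problem = make_problem(c=(10.0, 20.0), d0=(478, 400), rate=0.06, population=10000)
        zero = np.zeros((1, 2), dtype=int)
        assert horizon_bed_floor(zero, problem) == pytest.approx(878 - 600)

    def test_zero_rate_slack_is_total_beds(self, make_problem):
        problem = make_problem(c=(10.0,), d0=(55,), rate=0.0)
        assert horizon_bed_floor(np.zeros((1, 1)), problem) == pytest.approx(55)

    def test_empty_system_slack_is_negative_requirement(self, make_problem):
        problem = make_problem(c=(10.0,), d0=(0,), rate=0.05, population=1000)
        assert horizon_bed_floor(np.zeros((1, 1)), problem) == pytest.approx(-50)

    def test_raw_coefficient_used_not_ceiling(self, make_problem):
        problem = make_problem(c=(10.4,), d0=(0,), rate=0.0)
        plan = np.array([[2]])
        assert horizon_bed_floor(plan, problem) == pytest.approx(20.8)


class TestGradeShareFloors:
    def test_equal_stocks_hold_their_share(self, make_problem):
        problem = make_problem(
            c=(10.0,) * 5, a=(1.0,) * 5, b=(1.0,) * 5, d0=(100,) * 5, p=(0.15,) * 5
        )
        slacks = grade_share_floors(np.zeros((1, 5)), problem)
        assert slacks == pytest.approx([25.0] * 5)

    def test_zero_share_slack_equals_grade_beds(self, make_problem):
        problem = make_problem(c=(10.0, 10.0), d0=(30, 70))
        assert grade_share_floors(np.zeros((1, 2)), problem) == pytest.approx([30, 70])

    def test_concentration_in_one_grade_violates_others(self, make_problem):
        problem = make_problem(
            c=(10.0,) * 5, a=(1.0,) * 5, b=(1.0,) * 5, d0=(1000, 0, 0, 0, 0), p=(0.15,) * 5
        )
        slacks = grade_share_floors(np.zeros((1, 5)), problem)
        assert slacks[1:] == pytest.approx([-150.0] * 4)


class TestCumulativeBeds:
    def test_running_sum_single_grade(self, make_problem):
        problem = make_problem(c=(10.0,), d0=(5,), n_cycles=3)
        plan = np.array([[1], [2], [0]])
        got = [cumulative_beds(plan, problem, t)[0] for t in range(4)]
        assert got == pytest.approx([5, 15, 35, 35])

    def test_zero_plan_keeps_initial_stock(self, qinhuai):
        zero = np.zeros((5, 5))
        for t in range(6):
            assert cumulative_beds(zero, qinhuai, t).tolist() == [0, 1596, 1352, 525, 175]

    def test_cycle_out_of_range(self, qinhuai):
        with pytest.raises(ValueError):
            cumulative_beds(np.zeros((5, 5)), qinhuai, 6)

    def test_conservation(self, make_problem):
        """Final stock minus initial stock equals c * plan column sums."""
        rng = np.random.default_rng(7)
        problem = make_problem(
            c=(12.5, 3.0, 7.0), a=(1, 1, 1), b=(1, 1, 1), d0=(10, 20, 30), n_cycles=4
        )
        plan = rng.integers(0, 6, size=(4, 3))
        final = cumulative_beds(plan, problem, 4)
        expected = problem.grades.beds * plan.sum(axis=0)
        assert final - problem.district.initial_beds == pytest.approx(expected)


class TestPerCycleFloors:
    def test_slack_against_cycle_targets(self, make_problem):
        problem = make_problem(
            c=(10.0,),
            d0=(0,),
            n_cycles=5,
            rates=(0.048, 0.051, 0.055, 0.059, 0.063),
            reference_population=10000.0,
        )
        plan = np.array([[50], [0], [0], [0], [0]])
        slacks = per_cycle_bed_floors(plan, problem)
        assert slacks[0] == pytest.approx(500 - 480)
        assert slacks[1] == pytest.approx(500 - 510)

    def test_zero_rates_slacks_equal_cumulative_totals(self, make_problem):
        problem = make_problem(
            c=(10.0,), d0=(5,), n_cycles=3, rates=(0, 0, 0), reference_population=1.0
        )
        plan = np.array([[1], [2], [0]])
        assert per_cycle_bed_floors(plan, problem) == pytest.approx([15, 35, 35])

    def test_per_cycle_share_floors_use_cumulative_stock(self, make_problem):
        problem = make_problem(
            c=(10.0, 10.0),
            d0=(100, 100),
            p=(0.15, 0.15),
            n_cycles=2,
            rates=(0.0, 0.0),
            reference_population=1.0,
        )
        plan = np.array([[0, 0], [0, 80]])
        slacks = per_cycle_share_floors(plan, problem)
        assert slacks[0] == pytest.approx([70.0, 70.0])  # 100 - 0.15 * 200
        assert slacks[1] == pytest.approx([100 - 150, 900 - 150])


class TestEvaluate:
    def test_zero_plan_on_satisfied_problem(self, make_problem):
        problem = make_problem(c=(10.0,), d0=(100,), rate=0.05, population=1000)
        pair, report = evaluate(np.zeros((1, 1)), problem)
        assert (pair.neg_benefit, pair.cost) == (0.0, 0.0)
        assert report.feasible and report.total_violation == 0

    def test_zero_plan_on_unmet_floor(self, make_problem):
        problem = make_problem(c=(10.0,), d0=(0,), rate=0.05, population=1000)
        _, report = evaluate(np.zeros((1, 1)), problem)
        assert not report.feasible
        assert report.total_violation == pytest.approx(50)

    def test_objectives_match_components(self, qinhuai):
        rng = np.random.default_rng(3)
        plan = rng.integers(0, 4, size=(5, 5))
        pair, _ = evaluate(plan, qinhuai)
        assert pair.economic_benefit == pytest.approx(economic_benefit(plan, qinhuai))
        assert pair.social_cost == pytest.approx(social_cost(plan, qinhuai))

    def test_feasibility_iff_zero_violation(self, qinhuai):
        rng = np.random.default_rng(4)
        for _ in range(20):
            plan = rng.integers(0, 3, size=(5, 5))
            _, report = evaluate(plan, qinhuai)
            assert report.feasible == (report.total_violation <= 1e-9)


plans_2x3 = hnp.arrays(np.int64, (2, 3), elements=st.integers(0, 30))


def _algebra_problem(rate=0.0):
    from bedplan.model import DistrictState, PlanningProblem

    grades = GradeParameters(
        cost=(30.0, 11.0, 4.0), income=(50.0, 21.0, 6.0),
        beds=(9.0, 5.0, 2.0), min_share=(0.0, 0.0, 0.0),
    )
    district = DistrictState("algebra", np.zeros(3, dtype=np.int64), np.array([10, 0, 3]))
    return PlanningProblem(
        district=district, grades=grades, n_cycles=2,
        bed_rate_targets=np.array([rate]), horizon_population=1000.0,
    )


class TestAlgebraicProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(x=plans_2x3, y=plans_2x3)
    def test_linearity(self, x, y):
        """F1 and F2 are additive in plans."""
        problem = _algebra_problem()
        ox, _ = evaluate_batch(x[None].astype(float), problem)
        oy, _ = evaluate_batch(y[None].astype(float), problem)
        oxy, _ = evaluate_batch((x + y)[None].astype(float), problem)
        assert oxy[0] == pytest.approx(ox[0] + oy[0])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(x=plans_2x3, i=st.integers(0, 1), j=st.integers(0, 2))
    def test_monotonicity(self, x, i, j):
        """One more institution never lowers F1, F2, or a bed-floor slack."""
        problem = _algebra_problem(rate=0.1)
        bigger = x.copy()
        bigger[i, j] += 1
        assert economic_benefit(bigger, problem) >= economic_benefit(x, problem)
        assert social_cost(bigger, problem) >= social_cost(x, problem)
        assert horizon_bed_floor(bigger, problem) >= horizon_bed_floor(x, problem)


class TestValidation:
    def test_shares_exceeding_unity_rejected(self):
        with pytest.raises(ValueError, match="shares sum"):
            GradeParameters(
                cost=(1, 1), income=(1, 1), beds=(10, 10), min_share=(0.6, 0.5)
            )

    def test_plan_matrix_rejects_negative_and_fractional(self):
        with pytest.raises(ValueError):
            PlanMatrix(np.array([[-1, 0]]))
        with pytest.raises(ValueError):
            PlanMatrix(np.array([[0.5, 0]]))

    def test_default_bounds_cover_requirement(self, qinhuai):
        bounds = qinhuai.bounds()
        c = qinhuai.grades.beds
        assert ((bounds[0] * c) >= qinhuai.required_new_beds() - c).all()
        assert (bounds >= 0).all()
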