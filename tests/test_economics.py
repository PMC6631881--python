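"""Discounting, QALYs/HALYs, care costs, ICER/ROI and payback time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import qalysim as qs
from qalysim.economics import (
    DiscountSpec,
    EconomicSummary,
    cost_effectiveness,
    discount_stream,
    intervention_budget_for_icer,
    qalys,
    return_on_investment,
    time_to_cost_saving,
)
from qalysim.epidata import UndefinedComparisonError


class TestDiscounting:
    def test_rate_zero_is_plain_sum(self):
        assert discount_stream([3.0, 4.0, 5.0], DiscountSpec(0.0)) == 12.0

    def test_second_year_single_payment(self):
        assert discount_stream([0.0, 100.0], DiscountSpec(0.015)) == \
            pytest.approx(100.0 / 1.015, rel=1e-9)

    def test_constant_stream_matches_annuity_closed_form(self):
        got = discount_stream(np.ones(10), DiscountSpec(0.015))
        closed = (1 - 1.015 ** -10) / (1 - 1 / 1.015)
        assert got == pytest.approx(closed, rel=1e-12)
        assert got == pytest.approx(9.36052, abs=5e-6)

    @given(st.floats(0.0, 0.2, allow_subnormal=False), st.integers(1, 50))
    def test_matches_explicit_sum_property(self, rate, years):
        # independent oracle: term-by-term summation
        got = discount_stream(np.ones(years), DiscountSpec(rate))
        explicit = sum(1.0 / (1.0 + rate) ** t for t in range(years))
        assert got == pytest.approx(explicit, rel=1e-12)


class TestHealthOutcomes:
    def test_perfect_health_gives_discounted_person_years(self, tiny_inputs_factory):
        inputs = tiny_inputs_factory(count=500.0, mortality=0.1, utility=1.0)
        traj = qs.run_cohort(inputs, None, 5)
        spec = DiscountSpec(0.015)
        expected = discount_stream(traj.person_years.sum(axis=0), spec)
        assert qalys(traj, spec) == pytest.approx(expected, rel=1e-12)

    def test_zero_utility_gives_zero_qalys(self, tiny_inputs_factory):
        inputs = tiny_inputs_factory(count=500.0, mortality=0.1, utility=0.0)
        traj = qs.run_cohort(inputs, None, 5)
        assert qalys(traj, DiscountSpec()) == 0.0

    def test_identical_arms_have_zero_qaly_difference(self, inputs):
        spec = DiscountSpec()
        a = qs.run_cohort(inputs, None, 5)
        b = qs.run_cohort(inputs, {d: 1.0 for d in inputs.diseases}, 5)
        assert qalys(a, spec) - qalys(b, spec) == 0.0

    def test_halys_equal_qalys_under_definitional_mapping(self, inputs):
        spec = DiscountSpec()
        traj = qs.run_cohort(inputs, None, 10)
        decrements = dict(zip(inputs.registry["disease"],
                              inputs.registry["utility_decrement"]))
        si = inputs.single_year()
        background = si.utilities.assign(
            background_disability=1.0 - si.utilities["baseline_utility"])
        h = qs.halys(traj, inputs, spec,
                     disability_per_prevalent_case=decrements,
                     background_disability=background)
        q = qalys(traj, spec)
        assert h == pytest.approx(q, rel=1e-9)

    def test_zero_disability_halys_are_discounted_person_years(self, tiny_inputs_factory):
        inputs = tiny_inputs_factory(count=200.0, mortality=0.05)
        traj = qs.run_cohort(inputs, None, 4)
        spec = DiscountSpec(0.015)
        expected = discount_stream(traj.person_years.sum(axis=0), spec)
        assert qs.halys(traj, inputs, spec) == pytest.approx(expected, rel=1e-12)


class TestCareCosts:
    def test_prevalent_case_cost_direct_product(self, tiny_inputs_factory):
        # 100 persons, no mortality -> 100 person-years, prevalence 0.1 at
        # 1000/case-year: 10,000 per sex per year
        inputs = tiny_inputs_factory(count=100.0, prevalence=0.1, nhs_cost=1000.0)
        traj = qs.run_cohort(inputs, None, 1)
        costs = qs.care_costs(traj, inputs, DiscountSpec(0.0))
        assert costs.nhs_total == pytest.approx(2 * 10_000.0)
        assert costs.social_total == 0.0

    def test_all_zero_inputs_cost_nothing(self, tiny_inputs_factory):
        inputs = tiny_inputs_factory(count=100.0)
        traj = qs.run_cohort(inputs, None, 3)
        costs = qs.care_costs(traj, inputs, DiscountSpec())
        assert costs.nhs_total == 0.0 and costs.social_total == 0.0

    def test_social_cost_falls_as_utility_rises(self, tiny_inputs_factory):
        base = tiny_inputs_factory(count=100.0, utility=0.7, eligibility=0.2,
                                   base_monthly=1000.0, sensitivity=2.0)
        better = tiny_inputs_factory(count=100.0, utility=0.9, eligibility=0.2,
                                     base_monthly=1000.0, sensitivity=2.0)
        spec = DiscountSpec(0.0)
        c_low = qs.care_costs(qs.run_cohort(base, None, 1), base, spec)
        c_high = qs.care_costs(qs.run_cohort(better, None, 1), better, spec)
        assert c_high.social_total < c_low.social_total


def _summary(d_qaly, d_cost, c_i=1.0, nhs=0.0, social=0.0):
    # minimal consistent summary: C_a fixed, C_b derived
    c_a = 1_000.0
    return EconomicSummary(
        e_a=100.0, e_b=100.0 + d_qaly, c_a=c_a, c_b=c_a + d_cost, c_i=c_i,
        nhs_saving=nhs, social_saving=social,
        industry_cost=c_i, government_cost=0.0, horizon=10, discount_rate=0.015)


class TestCostEffectiveness:
    def test_icer_is_cost_per_qaly_quotient(self):
        res = cost_effectiveness(_summary(2.0, 50_000.0))
        assert res.classification == "icer"
        assert res.icer == pytest.approx(25_000.0)

    def test_saving_money_and_gaining_health_is_dominant(self):
        res = cost_effectiveness(_summary(5.0, -10.0, c_i=100.0, nhs=60.0, social=50.0))
        assert res.classification == "dominant"
        assert res.roi == pytest.approx(1.1)
        assert res.roi_net == pytest.approx(-0.1)

    def test_cost_without_benefit_is_dominated(self):
        res = cost_effectiveness(_summary(0.0, 100.0))
        assert res.classification == "dominated"

    def test_null_comparison_raises(self):
        with pytest.raises(UndefinedComparisonError):
            cost_effectiveness(_summary(0.0, 0.0, c_i=0.0))

    def test_component_sum_validation(self):
        s = _summary(1.0, 10.0)
        s.government_cost = 99.0  # breaks c_i = industry + government
        with pytest.raises(AssertionError):
            s.validate()


class TestROI:
    def test_table_style_quotient(self):
        # savings and intervention-cost medians at the scale of a national
        # reformulation programme
        roi, roi_net = return_on_investment(141_701_342.0, 724_832_212.0, 598_039_731.0)
        assert roi == pytest.approx(1.449, abs=5e-4)
        assert roi_net == pytest.approx(1.0 - roi, rel=1e-12)

    def test_zero_savings(self):
        roi, roi_net = return_on_investment(0.0, 0.0, 100.0)
        assert roi == 0.0 and roi_net == 1.0

    def test_break_even(self):
        roi, _ = return_on_investment(60.0, 40.0, 100.0)
        assert roi == 1.0

    def test_zero_spend_rejected(self):
        with pytest.raises(ZeroDivisionError):
            return_on_investment(1.0, 1.0, 0.0)


class TestTimeToCostSaving:
    def test_no_savings_never_pays_back(self):
        assert time_to_cost_saving([0, 0, 0], [100, 0, 0]) is None

    def test_cumulative_crossing(self):
        assert time_to_cost_saving([0, 60, 60], [100, 0, 0]) == 3

    def test_immediate_payback(self):
        assert time_to_cost_saving([150, 0, 0], [100, 0, 0]) == 1


class TestBudgetForThreshold:
    def test_budget_recovers_target_icer(self):
        budget = intervention_budget_for_icer(30_000.0, 1597.0, 10_402_110.0, 14_181_040.0)
        # plugging the budget back in gives the threshold ICER
        icer = (budget - 10_402_110.0 - 14_181_040.0) / 1597.0
        assert icer == pytest.approx(30_000.0, rel=1e-12)


class TestHorizonDirection:
    def test_delta_qalys_grow_with_horizon_for_beneficial_scenario(
            self, inputs, salt_scenario):
        gains = []
        for horizon in (1, 5, 10):
            res = qs.evaluate_scenario(inputs, salt_scenario, horizon=horizon)
            gains.append(res.summary.delta_qalys)
        assert gains[0] <= gains[1] <= gains[2]
        assert gains[2] > 0
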