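"""Scenario builders: salt targets, cost streams, leisure perturbations."""

import numpy as np
import pandas as pd
import pytest

import qalysim as qs
from qalysim.epidata import BoundViolationError
from qalysim.scenarios import (
    FOOD_DIARY_COLUMNS,
    PhaseInSchedule,
    annual_monitoring_cost,
    apply_salt_targets,
    round_half_up,
    salt_intervention_costs,
    validate_food_diary,
)


def _diary(rows):
    return pd.DataFrame(rows, columns=FOOD_DIARY_COLUMNS)



class TestApplySaltTargets:
    def test_compliant_diary_yields_zero_shift(self):
        diary = _diary([
            ("p1", "male", 40, 5, "bread", 100.0, 1.0, 1.0),
            ("p2", "male", 40, 5, "bread", 150.0, 1.0, 1.0),
        ])
        shift = apply_salt_targets(diary)
        assert (shift.table["delta_mean"] == 0).all()
        assert (shift.table["se_delta"] == 0).all()

    def test_single_person_arithmetic(self):
        # 200 g/day of a group falling 3.0 -> 2.5 g/100 g: delta = -1.0 g/day
        diary = _diary([("p1", "male", 40, 5, "bread", 200.0, 3.0, 2.5)])
        shift = apply_salt_targets(diary)
        assert shift.table["delta_mean"].iloc[0] == pytest.approx(-1.0)

    def test_two_person_mean_and_standard_error(self):
        diary = _diary([
            ("p1", "male", 40, 5, "bread", 200.0, 3.0, 2.5),
            ("p2", "male", 40, 5, "bread", 400.0, 3.0, 2.5),
        ])
        shift = apply_salt_targets(diary)
        assert shift.table["delta_mean"].iloc[0] == pytest.approx(-1.5)
        assert shift.table["se_delta"].iloc[0] == pytest.approx(0.5, rel=1e-6)

    def test_scaling_density_gap_scales_shift_linearly(self, microdata):
        diary = microdata["diary"]
        shift1 = apply_salt_targets(diary)
        halved = diary.copy()
        halved["target_salt_density"] = halved["baseline_salt_density"] - 0.5 * (
            halved["baseline_salt_density"] - halved["target_salt_density"])
        shift2 = apply_salt_targets(halved)
        np.testing.assert_allclose(
            shift2.table["delta_mean"], 0.5 * shift1.table["delta_mean"], rtol=1e-9)

    def test_raised_target_rejected(self):
        diary = _diary([("p1", "male", 40, 5, "bread", 100.0, 1.0, 1.2)])
        with pytest.raises(BoundViolationError, match="target"):
            validate_food_diary(diary)


class TestSaltCosts:
    def test_industry_total_is_products_times_unit_cost(self):
        stream = salt_intervention_costs(n_products=20_000, cost_per_product=29_953.0)
        assert stream.total(payers=("industry",)) == pytest.approx(599_060_000.0)

    def test_annual_monitoring_from_components(self):
        m = annual_monitoring_cost(91_588.0, 327_289.0, 2)
        assert m == pytest.approx(255_232.5)
        assert round_half_up(m) == 255_233.0

    def test_three_year_phase_in_splits_industry_cost_in_thirds(self):
        stream = salt_intervention_costs(horizon=10)
        industry = stream.frame["industry"].to_numpy()
        assert industry[0] == pytest.approx(599_060_000.0 / 3)
        np.testing.assert_allclose(industry[:3], industry[0])
        assert (industry[3:] == 0).all()

    def test_one_year_phase_in_front_loads_everything(self):
        stream = salt_intervention_costs(phase_in=PhaseInSchedule((1.0,)), horizon=10)
        industry = stream.frame["industry"].to_numpy()
        assert industry[0] == pytest.approx(599_060_000.0)
        assert (industry[1:] == 0).all()

    def test_government_costs_run_for_the_full_horizon(self):
        stream = salt_intervention_costs(horizon=10)
        gov = stream.frame["government"].to_numpy()
        np.testing.assert_allclose(gov, 255_232.5 + 570_892.0)

    def test_phase_in_validation(self):
        with pytest.raises(BoundViolationError):
            PhaseInSchedule((0.5, 0.4))
        with pytest.raises(BoundViolationError):
            PhaseInSchedule((0.5, -0.1, 0.6))
        cum = PhaseInSchedule((1 / 3, 1 / 3, 1 / 3)).cumulative(5)
        np.testing.assert_allclose(cum, [1 / 3, 2 / 3, 1.0, 1.0, 1.0])


class TestLeisureScenario:
    def test_zero_participation_has_no_effect_and_no_cost(self, microdata, inputs):
        part = microdata["pa_participation"].copy()
        part["participation"] = 0.0
        scenario = qs.build_leisure_scenario(
            microdata["pa_baseline"], part, microdata["pa_transitions"],
            inputs.population)
        pd.testing.assert_frame_equal(
            scenario.exposure.baseline, scenario.exposure.scenario)
        assert scenario.costs.total() == 0.0

    def test_per_participant_cost_stream(self, microdata, inputs):
        scenario = qs.build_leisure_scenario(
            microdata["pa_baseline"], microdata["pa_participation"],
            microdata["pa_transitions"], inputs.population,
            cost_y1=53.80, cost_later=29.80, horizon=4)
        participants = scenario.cost_model["participants"]
        gov = scenario.costs.frame["government"].to_numpy()
        assert gov[0] == pytest.approx(participants * 53.80)
        np.testing.assert_allclose(gov[1:], participants * 29.80)

    def test_million_participants_stream(self, microdata):
        # direct check of the printed-cost arithmetic at a round headcount
        from qalysim.scenarios import _per_participant_stream
        stream = _per_participant_stream(1_000_000, 53.80, 29.80, 3)
        np.testing.assert_allclose(
            stream.frame["government"], [53.8e6, 29.8e6, 29.8e6])

    def test_identity_transitions_with_positive_cost_are_dominated(self, inputs, microdata):
        ident = pd.DataFrame(np.eye(4), columns=list(qs.CATEGORIES))
        ident.insert(0, "from_category", list(qs.CATEGORIES))
        scenario = qs.build_leisure_scenario(
            microdata["pa_baseline"], microdata["pa_participation"], ident,
            inputs.population, cost_uncertainty=False)
        result = qs.evaluate_scenario(inputs, scenario)
        assert result.summary.delta_qalys == 0.0
        assert result.summary.c_i > 0
        assert result.ce.classification == "dominated"

    def test_cost_stream_invariant_to_stratum_order(self, microdata, inputs):
        shuffled = microdata["pa_baseline"].sample(frac=1.0, random_state=0)
        part = microdata["pa_participation"].sample(frac=1.0, random_state=1)
        s1 = qs.build_leisure_scenario(
            microdata["pa_baseline"], microdata["pa_participation"],
            microdata["pa_transitions"], inputs.population)
        s2 = qs.build_leisure_scenario(
            shuffled, part, microdata["pa_transitions"], inputs.population)
        assert s1.costs.total() == pytest.approx(s2.costs.total(), rel=1e-12)
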