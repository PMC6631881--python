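import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import qalysim as qs
from qalysim.epidata import STRATUM_COLS

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def synth_config():
    return qs.SynthConfig(seed=1)


@pytest.fixture(scope="session")
def inputs(synth_config):
    return qs.generate_inputs(synth_config)


@pytest.fixture(scope="session")
def microdata(synth_config):
    diary, pa_baseline, pa_participation, pa_transitions = qs.generate_microdata(synth_config)
    return {"diary": diary, "pa_baseline": pa_baseline,
            "pa_participation": pa_participation, "pa_transitions": pa_transitions}


@pytest.fixture(scope="session")
def salt_scenario(microdata):
    return qs.build_salt_scenario(microdata["diary"])


@pytest.fixture(scope="session")
def leisure_scenario(microdata, inputs):
    return qs.build_leisure_scenario(
        microdata["pa_baseline"], microdata["pa_participation"],
        microdata["pa_transitions"], inputs.population)


@pytest.fixture(scope="session")
def salt_result(inputs, salt_scenario):
    return qs.evaluate_scenario(inputs, salt_scenario)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A small on-disk bundle for loader and CLI tests."""
    d = tmp_path_factory.mktemp("bundle")
    qs.write_bundle(qs.SynthConfig(seed=1, diary_persons_per_stratum=10), d)
    return d


def make_tiny_inputs(n_strata_per_sex=1, age_start=60, count=100.0,
                     mortality=0.0, incidence=0.0, prevalence=0.0,
                     case_fatality=0.0, remission=0.0,
                     nhs_cost=0.0, utility=1.0, background_disability=0.0,
                     unrelated_nhs=0.0, unrelated_social=0.0,
                     eligibility=0.0, base_monthly=0.0, sensitivity=0.0,
                     utility_decrement=0.0, disability=0.0,
                     diseases=("ihd",)) -> qs.ModelInputs:
    """Hand-built single-year bundle with fully controlled rates, for exact
    unit checks of the cohort engine and the economics."""
    rows = [(sex, age_start + k, 1)
            for sex in ("male", "female") for k in range(n_strata_per_sex)]
    strata = pd.DataFrame(rows, columns=STRATUM_COLS)
    epi = pd.concat([
        strata.assign(disease=d, incidence=incidence, prevalence=prevalence,
                      case_fatality=case_fatality, remission=remission,
                      nhs_annual_cost_per_prevalent_case=nhs_cost)
        for d in diseases], ignore_index=True)
    registry = pd.DataFrame({
        "disease": list(diseases),
        "affected_by": "none",
        "utility_decrement": utility_decrement,
        "disability_per_prevalent_case": disability,
    })
    return qs.ModelInputs(
        population=strata.assign(count=count),
        mortality=strata.assign(all_cause_mortality=mortality),
        disease_epi=epi,
        registry=registry,
        utilities=strata.assign(
            baseline_utility=utility, background_disability=background_disability,
            unrelated_nhs_cost=unrelated_nhs, unrelated_social_cost=unrelated_social),
        social_care=strata.assign(
            eligibility=eligibility, base_monthly_cost=base_monthly,
            utility_sensitivity=sensitivity),
    )


@pytest.fixture
def tiny_inputs_factory():
    return make_tiny_inputs
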