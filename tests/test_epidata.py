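"""Input schemas, validation failures, band expansion and round trips."""

import logging

import numpy as np
import pandas as pd
import pytest

import qalysim as qs
from qalysim.epidata import (
    STRATUM_COLS,
    BandContiguityError,
    BoundViolationError,
    MissingColumnError,
    NonNumericCellError,
    StratumMismatchError,
)


def _read_lines(path):
    with open(path, "rb") as fh:
        return fh.read()


class TestLoader:
    def test_generator_bundle_loads_with_zero_warnings(self, bundle_dir, caplog):
        with caplog.at_level(logging.WARNING, logger="qalysim"):
            inputs = qs.load_inputs(bundle_dir)
        assert not caplog.records
        assert qs.validate_consistency(inputs).ok
        assert set(inputs.registry["disease"]) >= set(qs.CORE_DISEASES)

    def test_out_of_range_prevalence_names_disease_and_stratum(self, bundle_dir, tmp_path):
        epi = pd.read_csv(bundle_dir / "disease_epi.csv")
        epi.loc[0, "prevalence"] = 1.2
        bad = tmp_path / "bad"
        bad.mkdir()
        for f in bundle_dir.glob("*.csv"):
            (bad / f.name).write_bytes(f.read_bytes())
        epi.to_csv(bad / "disease_epi.csv", index=False)
        with pytest.raises(BoundViolationError) as err:
            qs.load_inputs(bad)
        msg = str(err.value)
        assert "disease_epi.csv" in msg and "prevalence" in msg
        assert epi.loc[0, "disease"] in msg and str(epi.loc[0, "age_start"]) in msg

    def test_missing_female_strata_is_a_stratum_mismatch(self, bundle_dir, tmp_path):
        mort = pd.read_csv(bundle_dir / "mortality.csv")
        bad = tmp_path / "bad"
        bad.mkdir()
        for f in bundle_dir.glob("*.csv"):
            (bad / f.name).write_bytes(f.read_bytes())
        mort[mort["sex"] == "male"].to_csv(bad / "mortality.csv", index=False)
        with pytest.raises(StratumMismatchError, match="mortality.csv"):
            qs.load_inputs(bad)

    def test_missing_column_and_non_numeric_cell(self, bundle_dir, tmp_path):
        bad = tmp_path / "bad"
        bad.mkdir()
        for f in bundle_dir.glob("*.csv"):
            (bad / f.name).write_bytes(f.read_bytes())
        pop = pd.read_csv(bundle_dir / "population.csv")
        pop.drop(columns="count").to_csv(bad / "population.csv", index=False)
        with pytest.raises(MissingColumnError, match="count"):
            qs.load_inputs(bad)
        pop = pop.astype({"count": object})
        pop.loc[2, "count"] = "not-a-number"
        pop.to_csv(bad / "population.csv", index=False)
        with pytest.raises(NonNumericCellError) as err:
            qs.load_inputs(bad)
        assert err.value.row == 2 and err.value.column == "count"

    def test_round_trip_is_byte_identical(self, bundle_dir, tmp_path):
        inputs = qs.load_inputs(bundle_dir)
        out = tmp_path / "rt"
        qs.write_inputs(inputs, out)
        for f in sorted(out.glob("*.csv")):
            assert _read_lines(f) == _read_lines(bundle_dir / f.name), f.name


class TestExpandAgeBands:
    def test_rates_copy_piecewise_constant(self):
        band = pd.DataFrame({"sex": ["male"], "age_start": [15], "age_width": [5],
                             "rate": [0.01]})
        out = qs.expand_age_bands(band)
        assert list(out["age_start"]) == [15, 16, 17, 18, 19]
        assert (out["rate"] == 0.01).all() and (out["age_width"] == 1).all()

    def test_counts_split_evenly(self):
        band = pd.DataFrame({"sex": ["male"], "age_start": [15], "age_width": [5],
                             "count": [1000.0]})
        out = qs.expand_age_bands(band, count_cols=("count",))
        assert (out["count"] == 200.0).all()
        assert out["count"].sum() == 1000.0

    def test_gap_between_bands_is_an_error(self):
        band = pd.DataFrame({"sex": ["male", "male"], "age_start": [15, 25],
                             "age_width": [5, 5], "rate": [0.01, 0.02]})
        with pytest.raises(BandContiguityError, match="gap"):
            qs.expand_age_bands(band)

    def test_overlap_is_an_error(self):
        band = pd.DataFrame({"sex": ["male", "male"], "age_start": [15, 18],
                             "age_width": [5, 5], "rate": [0.01, 0.02]})
        with pytest.raises(BandContiguityError, match="overlap"):
            qs.expand_age_bands(band)

    def test_expansion_preserves_population_totals_and_band_means(self, inputs):
        single = inputs.single_year()
        assert single.population["count"].sum() == pytest.approx(
            inputs.population["count"].sum(), rel=1e-12)
        # band mean of an expanded rate equals the band value
        band_mean = single.mortality.groupby("sex")["all_cause_mortality"].mean()
        orig_mean = inputs.mortality.groupby("sex")["all_cause_mortality"].mean()
        pd.testing.assert_series_equal(band_mean, orig_mean)


class TestConsistency:
    def test_constructed_violation_is_flagged(self, inputs):
        broken = qs.ModelInputs(
            population=inputs.population, mortality=inputs.mortality,
            disease_epi=inputs.disease_epi.assign(
                case_fatality=inputs.disease_epi["case_fatality"] * 50.0),
            registry=inputs.registry, utilities=inputs.utilities,
            social_care=inputs.social_care)
        report = qs.validate_consistency(broken)
        assert report.violations
        assert all(v.sex in ("male", "female") for v in report.violations)

    def test_empty_registry_is_vacuously_consistent(self, inputs):
        empty = qs.ModelInputs(
            population=inputs.population, mortality=inputs.mortality,
            disease_epi=inputs.disease_epi.iloc[0:0],
            registry=inputs.registry.iloc[0:0],
            utilities=inputs.utilities, social_care=inputs.social_care)
        assert qs.validate_consistency(empty).ok


def test_stratum_invariants():
    with pytest.raises(BoundViolationError):
        qs.Stratum(sex="other", age_start=15)
    with pytest.raises(BoundViolationError):
        qs.Stratum(sex="male", age_start=15, age_width=3)
    s = qs.Stratum(sex="male", age_start=15, age_width=5)
    assert s.age_start == 15


def test_hazard_conversion_bounds():
    risks = qs.hazard_to_annual_risk(np.array([0.0, 0.01, 5.0]))
    assert risks[0] == 0.0
    assert 0 < risks[1] < 0.01
    assert risks[2] < 1.0
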