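"""Seeded generator of a complete, internally consistent synthetic
England-like input bundle.

The generator emulates the statistical structure of the real sources — a
national diet survey's per-person food-group diaries with above-target salt
densities, a population activity survey's four-category distributions,
national life tables and disease registers — without calibrating to any
real statistic.  Age profiles use simple parametric curves (Gompertz-style
exponential growth for mortality and incidence, linear decline for
utilities, logistic care eligibility): realism is secondary to validity
(all rates in [0, 1], summed disease deaths strictly below all-cause
mortality, monotone age gradients) and speed.

Everything is deterministic in the seed: the same config produces a
byte-identical bundle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epidata import (
    ALL_DISEASES,
    CATEGORIES,
    SEXES,
    STRATUM_COLS,
    ModelInputs,
    canonical_sort,
    write_inputs,
)

__all__ = ["SynthConfig", "generate_inputs", "generate_microdata", "write_bundle"]

# disease-specific curve parameters:
#   (incidence at age 15, exponential age slope, duration-like prevalence
#    multiplier, case fatality at 15, cf slope, remission, male factor)
_DISEASE_CURVES: dict[str, tuple] = {
    "ihd":               (2.0e-4, 0.070, 8.0, 0.010, 0.040, 0.00, 1.40),
    "stroke":            (1.2e-4, 0.075, 6.0, 0.015, 0.040, 0.00, 1.25),
    "type2_diabetes":    (1.0e-3, 0.045, 15.0, 0.003, 0.030, 0.00, 1.10),
    "breast_cancer":     (4.0e-4, 0.030, 5.0, 0.020, 0.025, 0.05, 0.005),
    "colorectal_cancer": (6.0e-5, 0.065, 4.0, 0.030, 0.025, 0.05, 1.20),
    "lung_cancer":       (4.0e-5, 0.070, 2.0, 0.150, 0.015, 0.02, 1.30),
    "stomach_cancer":    (2.0e-5, 0.065, 3.0, 0.060, 0.020, 0.03, 1.50),
    "liver_cancer":      (1.5e-5, 0.060, 2.0, 0.180, 0.010, 0.02, 1.60),
    "kidney_cancer":     (2.5e-5, 0.060, 4.0, 0.040, 0.020, 0.04, 1.40),
    "pancreatic_cancer": (1.5e-5, 0.065, 1.5, 0.250, 0.010, 0.01, 1.10),
    "liver_cirrhosis":   (8.0e-5, 0.040, 6.0, 0.050, 0.020, 0.01, 1.50),
}

# utility decrement / disability weight / NHS annual cost per prevalent case
_DISEASE_BURDEN: dict[str, tuple] = {
    "ihd":               (0.060, 0.070, 1600.0),
    "stroke":            (0.110, 0.130, 2600.0),
    "type2_diabetes":    (0.040, 0.049, 1100.0),
    "breast_cancer":     (0.090, 0.100, 3200.0),
    "colorectal_cancer": (0.095, 0.105, 3600.0),
    "lung_cancer":       (0.130, 0.150, 4200.0),
    "stomach_cancer":    (0.110, 0.125, 3800.0),
    "liver_cancer":      (0.130, 0.145, 4000.0),
    "kidney_cancer":     (0.090, 0.100, 3400.0),
    "pancreatic_cancer": (0.140, 0.160, 4400.0),
    "liver_cirrhosis":   (0.120, 0.135, 2900.0),
}

_PA_RR = {
    # sedentary, under_active, active, recommended (reference)
    "ihd":               (1.45, 1.25, 1.10, 1.0),
    "stroke":            (1.35, 1.20, 1.08, 1.0),
    "type2_diabetes":    (1.60, 1.35, 1.15, 1.0),
    "breast_cancer":     (1.15, 1.10, 1.05, 1.0),
    "colorectal_cancer": (1.25, 1.15, 1.08, 1.0),
}

# participant transition rows (sedentary row is identity: participants are
# never sedentary)
_PA_TRANSITIONS = np.array([
    [1.00, 0.00, 0.00, 0.00],
    [0.00, 0.45, 0.35, 0.20],
    [0.00, 0.00, 0.60, 0.40],
    [0.00, 0.00, 0.00, 1.00],
])

_FOOD_DENSITIES = np.array([1.6, 1.25, 0.95, 0.60, 0.35, 0.22])  # g salt /100 g
_FOOD_SHARES = np.array([0.24, 0.22, 0.18, 0.16, 0.12, 0.08])    # share of salt intake


@dataclass
class SynthConfig:
    """Knobs of the synthetic bundle; defaults emulate the English study
    conditions (2014 baseline year) at national population scale."""

    seed: int = 1
    age_min: int = 15
    age_max_band_start: int = 95
    band_width: int = 5
    population_scale: float = 1.0
    diseases: tuple = ALL_DISEASES
    # diary / salt exposure
    diary_persons_per_stratum: int = 120
    food_groups: int = 6
    mean_salt: dict = field(default_factory=lambda: {"male": 8.0, "female": 6.2})
    salt_reduction_frac: float = 0.15   # density cut in non-compliant groups
    compliant_groups: int = 1           # groups already meeting their target
    person_noise_sd: float = 0.25       # lognormal sd of per-person grams
    # social care cost model
    base_monthly_cost: float = 2700.0
    utility_sensitivity: float = 2.0

    def __post_init__(self):
        if self.population_scale <= 0 or self.diary_persons_per_stratum <= 0:
            raise ValueError("scales must be > 0")
        if not 0 <= self.compliant_groups <= self.food_groups:
            raise ValueError("compliant_groups must be within the food groups")
        if self.food_groups > len(_FOOD_DENSITIES):
            raise ValueError(f"at most {len(_FOOD_DENSITIES)} food groups supported")

    @property
    def band_starts(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max_band_start + 1, self.band_width)


def _strata_frame(config: SynthConfig) -> pd.DataFrame:
    rows = [(sex, int(a), config.band_width)
            for sex in SEXES for a in config.band_starts]
    return pd.DataFrame(rows, columns=STRATUM_COLS)


def _mid_ages(strata: pd.DataFrame) -> np.ndarray:
    return strata["age_start"].to_numpy() + (strata["age_width"].to_numpy() - 1) / 2.0


def generate_inputs(config: SynthConfig = SynthConfig()) -> ModelInputs:
    """Generate the full epidemiological bundle (population, mortality,
    disease epidemiology, registry, utilities, social care, and the salt/BP
    pathway parameter tables)."""
    rng = np.random.default_rng([config.seed, 101])
    strata = _strata_frame(config)
    age = _mid_ages(strata)
    rel_age = age - config.age_min
    male = (strata["sex"] == "male").to_numpy()

    # population: plateau through mid-adulthood, exponential decline beyond 45
    count = 1.8e6 * np.exp(-0.06 * np.maximum(age - 45.0, 0.0)) * config.population_scale
    population = strata.assign(count=count)

    # all-cause mortality: Gompertz-style growth, higher for men
    mort = 2.0e-4 * np.exp(0.085 * rel_age) * np.where(male, 1.2, 1.0)
    mort = np.clip(mort, 0.0, 0.6)
    mortality = strata.assign(all_cause_mortality=mort)

    # disease epidemiology
    epi_rows = []
    jitter = {d: rng.lognormal(0.0, 0.05, size=2) for d in config.diseases}
    for d in config.diseases:
        inc0, slope, duration, cf0, cf_slope, remission, male_factor = _DISEASE_CURVES[d]
        jit = np.where(male, jitter[d][0], jitter[d][1])
        inc = inc0 * np.exp(slope * rel_age) * np.where(male, male_factor, 1.0) * jit
        inc = np.clip(inc, 1e-9, 0.08)
        prev = np.clip(inc * duration, 0.0, 0.35)
        cf = np.clip(cf0 * np.exp(cf_slope * rel_age), 0.0, 0.5)
        _, _, nhs_cost = _DISEASE_BURDEN[d]
        cost = nhs_cost * (1.0 + 0.006 * rel_age)
        epi_rows.append(strata.assign(
            disease=d, incidence=inc, prevalence=prev, case_fatality=cf,
            remission=float(remission), nhs_annual_cost_per_prevalent_case=cost))
    epi = pd.concat(epi_rows, ignore_index=True)

    # guarantee a strictly positive residual: scale case fatalities so the
    # summed disease-death rate stays below half the all-cause rate
    dd = (epi["prevalence"] * epi["case_fatality"]).groupby(
        [epi[c] for c in STRATUM_COLS]).transform("sum")
    mort_aligned = epi[STRATUM_COLS].merge(
        mortality, on=STRATUM_COLS, how="left")["all_cause_mortality"]
    scale = np.minimum(1.0, 0.5 * mort_aligned.to_numpy()
                       / np.maximum(dd.to_numpy(), 1e-300))
    epi["case_fatality"] = epi["case_fatality"] * scale

    registry = pd.DataFrame({
        "disease": list(config.diseases),
        "affected_by": [
            "blood_pressure;physical_activity" if d in ("ihd", "stroke")
            else ("physical_activity" if d in _PA_RR else "none")
            for d in config.diseases],
        "utility_decrement": [_DISEASE_BURDEN[d][0] for d in config.diseases],
        "disability_per_prevalent_case": [_DISEASE_BURDEN[d][1] for d in config.diseases],
    })

    utilities = strata.assign(
        baseline_utility=np.clip(0.94 - 0.0028 * rel_age, 0.0, 1.0),
        background_disability=np.clip(0.05 + 0.0022 * rel_age, 0.0, 1.0),
        unrelated_nhs_cost=350.0 * np.exp(0.035 * rel_age),
        unrelated_social_cost=5.0 * np.exp(0.065 * rel_age),
    )

    social_care = strata.assign(
        eligibility=np.clip(0.45 / (1.0 + np.exp(-(age - 88.0) / 4.5)), 0.0, 1.0),
        base_monthly_cost=config.base_monthly_cost,
        utility_sensitivity=config.utility_sensitivity,
    )

    # salt -> SBP dose response (mmHg fall per g/day salt reduction)
    salt_sbp = strata.assign(mmhg_per_gram=np.where(male, 1.0, 0.889))

    # blood-pressure relative risks per +1 mmHg, attenuating with age
    atten = np.clip(1.0 - 0.7 * rel_age / 82.0, 0.25, 1.0)
    bp_rows = []
    for d, slope in (("ihd", 0.030), ("stroke", 0.040)):
        bp_rows.append(strata.assign(disease=d, rr_per_mmhg=1.0 + slope * atten))
    bp_rr = pd.concat(bp_rows, ignore_index=True)

    pa_rr = pd.DataFrame(
        [{"disease": d, **dict(zip(CATEGORIES, rr))} for d, rr in _PA_RR.items()])

    return ModelInputs(
        population=canonical_sort(population),
        mortality=canonical_sort(mortality),
        disease_epi=canonical_sort(epi),
        registry=registry,
        utilities=canonical_sort(utilities),
        social_care=canonical_sort(social_care),
        salt_sbp=canonical_sort(salt_sbp),
        bp_rr=canonical_sort(bp_rr),
        pa_rr=pa_rr,
    )


def generate_microdata(config: SynthConfig = SynthConfig()):
    """Generate the exposure microdata: a per-person food-group diary with
    above-target salt densities, and the four-category activity tables
    (baseline distribution, participation fractions, participant
    transitions).

    Returns ``(diary, pa_baseline, pa_participation, pa_transitions)``.
    """
    rng = np.random.default_rng([config.seed, 202])
    strata = _strata_frame(config)
    age = _mid_ages(strata)
    rel_age = age - config.age_min

    g = config.food_groups
    densities = _FOOD_DENSITIES[:g]
    shares = _FOOD_SHARES[:g] / _FOOD_SHARES[:g].sum()
    # the lowest-density groups are the already-compliant ones
    compliant = np.zeros(g, dtype=bool)
    if config.compliant_groups:
        compliant[g - config.compliant_groups:] = True
    target = np.where(compliant, densities,
                      densities * (1.0 - config.salt_reduction_frac))

    diary_rows = []
    noise_correction = np.exp(-config.person_noise_sd ** 2 / 2.0)
    for i, row in strata.iterrows():
        mean_salt = config.mean_salt[row["sex"]] * (1.15 - 0.003 * rel_age[i])
        base_grams = mean_salt * shares / densities * 100.0
        n = config.diary_persons_per_stratum
        noise = rng.lognormal(0.0, config.person_noise_sd, size=(n, g)) * noise_correction
        grams = base_grams[None, :] * noise
        for p in range(n):
            pid = f"{row['sex'][0]}{row['age_start']:02d}_{p:04d}"
            for j in range(g):
                diary_rows.append((pid, row["sex"], row["age_start"], row["age_width"],
                                   f"group_{j+1}", grams[p, j], densities[j], target[j]))
    diary = pd.DataFrame(diary_rows, columns=[
        "person_id", "sex", "age_start", "age_width", "food_group",
        "grams_per_day", "baseline_salt_density", "target_salt_density"])

    # activity distributions: younger and male strata more active
    male = (strata["sex"] == "male").to_numpy()
    sed = np.clip(0.16 + 0.0042 * rel_age, 0.0, 0.9) * np.where(male, 0.95, 1.05)
    rec = np.clip(0.54 - 0.0046 * rel_age, 0.02, 1.0) * np.where(male, 1.05, 0.90)
    under = 0.45 * (1.0 - sed - rec)
    active = 0.55 * (1.0 - sed - rec)
    dist = np.column_stack([sed, under, active, rec])
    dist = dist / dist.sum(axis=1, keepdims=True)
    pa_baseline = strata.copy()
    pa_baseline[list(CATEGORIES)] = dist

    participation = np.clip(0.13 * np.exp(-0.02 * rel_age), 0.0, 1.0) \
        * np.where(male, 0.92, 1.08)
    pa_participation = strata.assign(participation=participation)

    pa_transitions = pd.DataFrame(_PA_TRANSITIONS, columns=list(CATEGORIES))
    pa_transitions.insert(0, "from_category", list(CATEGORIES))

    return diary, pa_baseline, pa_participation, pa_transitions


def write_bundle(config: SynthConfig, directory: str | os.PathLike) -> ModelInputs:
    """Generate everything and write the full CSV bundle (epidemiology,
    pathway tables, food diary and activity tables) to ``directory``."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    inputs = generate_inputs(config)
    write_inputs(inputs, directory)
    diary, pa_baseline, pa_participation, pa_transitions = generate_microdata(config)
    diary.to_csv(os.path.join(directory, "food_diary.csv"), index=False,
                 lineterminator="\n")
    pa_baseline.to_csv(os.path.join(directory, "pa_baseline.csv"), index=False,
                       lineterminator="\n")
    pa_participation.to_csv(os.path.join(directory, "pa_participation.csv"),
                            index=False, lineterminator="\n")
    pa_transitions.to_csv(os.path.join(directory, "pa_transitions.csv"),
                          index=False, lineterminator="\n")
    return inputs
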