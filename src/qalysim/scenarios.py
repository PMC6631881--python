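"""Intervention scenario builders.

A :class:`Scenario` bundles a per-stratum risk-factor perturbation, a
phase-in schedule and payer-tagged cost streams.  Two builders mirror the
modelled interventions:

* **salt reformulation** — food-diary microdata are reformulated to target
  salt densities; the per-stratum mean change in salt intake (with its
  standard error) drives the blood-pressure pathway.  Industry bears the
  one-off reformulation cost (phased in, by default a third in each of the
  first three years); government bears annual monitoring (food-purchase
  panel data plus a biannual urinary sodium survey) and administration
  costs for the whole horizon.
* **leisure-centre access** — a participating fraction of the non-sedentary
  population moves between physical-activity categories according to a
  transition matrix; government pays a per-participant cost, higher in the
  first year.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .epidata import (
    CATEGORIES,
    SCHEMAS,
    STRATUM_COLS,
    BoundViolationError,
    InputValidationError,
    ModelInputs,
    canonical_sort,
    expand_age_bands,
    _SEX_ORDER,
)
from . import pathways
from .pathways import ContinuousExposureShift
from .uncertainty import ParameterDistribution, sample_parameter

__all__ = [
    "FOOD_DIARY_COLUMNS",
    "PhaseInSchedule",
    "CostStream",
    "ActivityPerturbation",
    "Scenario",
    "load_food_diary",
    "apply_salt_targets",
    "baseline_salt_means",
    "annual_monitoring_cost",
    "salt_intervention_costs",
    "build_salt_scenario",
    "build_full_salt_reduction_scenario",
    "build_leisure_scenario",
    "build_all_sedentary_scenario",
    "null_scenario",
    "round_half_up",
]

PAYERS = ("industry", "government", "nhs", "social_care")

FOOD_DIARY_COLUMNS = [
    "person_id", "sex", "age_start", "age_width", "food_group",
    "grams_per_day", "baseline_salt_density", "target_salt_density",
]

# Default salt-scenario cost inputs (2014 GBP): product reformulation cost,
# purchasing-panel subscription, biannual urinary sodium survey, and the
# NCD-costing-tool government administration estimate.
SALT_COST_DEFAULTS = dict(
    n_products=20_000,
    cost_per_product=29_953.0,
    kantar_annual=91_588.0,
    sodium_survey_cost=327_289.0,
    survey_period_years=2,
    admin_annual=570_892.0,
)

# Default leisure-scenario per-participant costs (2014 GBP, inflation
# adjusted) and their triangular uncertainty (min, mode, max).
LEISURE_COST_Y1 = (43.50, 53.80, 85.90)
LEISURE_COST_LATER = (24.00, 29.80, 48.10)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Commercial rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# schedule and cost-stream types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseInSchedule:
    """Fraction of the full effect (and of implementation cost) realised in
    each calendar year.  Fractions are in [0, 1] and sum to 1."""

    fractions: tuple[float, ...] = (1.0 / 3, 1.0 / 3, 1.0 / 3)

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if len(f) == 0 or (f < 0).any() or (f > 1).any():
            raise BoundViolationError("phase-in fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise BoundViolationError("phase-in fractions must sum to 1")

    def fraction_in_year(self, horizon: int) -> np.ndarray:
        out = np.zeros(horizon)
        n = min(len(self.fractions), horizon)
        out[:n] = self.fractions[:n]
        return out

    def cumulative(self, horizon: int) -> np.ndarray:
        """Cumulative fraction of the full effect in place in each year."""
        return np.minimum(np.cumsum(self.fraction_in_year(horizon)), 1.0)


@dataclass
class CostStream:
    """Undiscounted per-year, per-payer intervention cost amounts.

    ``frame`` is indexed by model year (1..horizon) with one column per
    payer in :data:`PAYERS` (missing payers are zero).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame.copy()
        for p in PAYERS:
            if p not in f.columns:
                f[p] = 0.0
        f = f[list(PAYERS)].astype(float)
        if (f[["industry", "government"]].to_numpy() < 0).any():
            raise BoundViolationError("intervention payer amounts must be >= 0")
        self.frame = f

    @property
    def horizon(self) -> int:
        return len(self.frame)

    def per_year(self, payers=PAYERS) -> np.ndarray:
        return self.frame[list(payers)].sum(axis=1).to_numpy()

    def total(self, payers=PAYERS) -> float:
        return float(self.per_year(payers).sum())

    def extended(self, horizon: int) -> "CostStream":
        """Pad with zero-cost years (or truncate) to the given horizon."""
        f = self.frame.reindex(range(1, horizon + 1), fill_value=0.0)
        return CostStream(f)


def zero_cost_stream(horizon: int) -> CostStream:
    return CostStream(pd.DataFrame(0.0, index=range(1, horizon + 1), columns=list(PAYERS)))


# ---------------------------------------------------------------------------
# scenario object
# ---------------------------------------------------------------------------

@dataclass
class ActivityPerturbation:
    """Baseline and post-intervention activity category distributions per
    stratum (columns: stratum columns + the four category shares)."""

    baseline: pd.DataFrame
    scenario: pd.DataFrame

    def __post_init__(self):
        for df in (self.baseline, self.scenario):
            pathways.validate_distribution(df[list(CATEGORIES)].to_numpy())


@dataclass
class Scenario:
    """A named intervention: one exposure perturbation, a phase-in schedule,
    payer-tagged costs, and an optional age mask limiting who is affected."""

    name: str
    kind: str  # "salt" | "leisure"
    exposure: ContinuousExposureShift | ActivityPerturbation
    phase_in: PhaseInSchedule
    costs: CostStream
    age_mask: tuple[int | None, int | None] | None = None
    uncertainty: dict[str, ParameterDistribution] = field(default_factory=dict)
    cost_model: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("salt", "leisure"):
            raise BoundViolationError(f"unknown scenario kind {self.kind!r}")
        want = ContinuousExposureShift if self.kind == "salt" else ActivityPerturbation
        if not isinstance(self.exposure, want):
            raise BoundViolationError(
                f"{self.kind} scenario requires a {want.__name__} perturbation")

    # -- effect ------------------------------------------------------------

    def _mask(self, strata: pd.DataFrame) -> np.ndarray:
        if self.age_mask is None:
            return np.ones(len(strata), dtype=bool)
        lo, hi = self.age_mask
        age = strata["age_start"].to_numpy()
        mask = np.ones(len(strata), dtype=bool)
        if lo is not None:
            mask &= age >= lo
        if hi is not None:
            mask &= age <= hi
        return mask

    def incidence_multipliers(self, inputs: ModelInputs,
                              horizon: int) -> dict[str, np.ndarray]:
        """Per-disease (S, T) incidence rate-ratio tables on the single-year
        strata of ``inputs``, with the phase-in schedule applied."""
        si = inputs.single_year()
        strata = si.population[STRATUM_COLS].reset_index(drop=True)
        mask = self._mask(strata)
        cum = self.phase_in.cumulative(horizon)

        if self.kind == "salt":
            if si.salt_sbp is None or si.bp_rr is None:
                raise InputValidationError(
                    "salt scenario requires salt_sbp_model.csv and bp_disease_rr.csv")
            shift_sy = ContinuousExposureShift(expand_age_bands(self.exposure.table))
            sbp = pathways.salt_to_sbp_shift(shift_sy, si.salt_sbp)
            sbp = strata.merge(sbp, on=STRATUM_COLS, how="left")
            delta = sbp["delta_sbp"].fillna(0.0).to_numpy() * mask
            mult = {}
            for d, rr_sub in si.bp_rr.groupby("disease", sort=False):
                rr = strata.merge(rr_sub, on=STRATUM_COLS, how="left")["rr_per_mmhg"]
                rr = rr.fillna(1.0).to_numpy()
                mult[d] = pathways.rate_ratio_from_bp_shift(
                    delta[:, None] * cum[None, :], rr[:, None])
            return mult

        # leisure: categorical distributions -> PIF per disease
        if si.pa_rr is None:
            raise InputValidationError("leisure scenario requires pa_rr.csv")
        base = strata.merge(expand_age_bands(self.exposure.baseline),
                            on=STRATUM_COLS, how="left")
        scen = strata.merge(expand_age_bands(self.exposure.scenario),
                            on=STRATUM_COLS, how="left")
        b = base[list(CATEGORIES)].to_numpy()
        s = scen[list(CATEGORIES)].to_numpy()
        s = np.where(mask[:, None], s, b)  # outside the age mask: no change
        mult = {}
        for _, row in si.pa_rr.iterrows():
            rr = row[list(CATEGORIES)].to_numpy(dtype=float)
            before = b @ rr
            after = s @ rr
            pif = (before - after) / before
            mult[row["disease"]] = 1.0 - pif[:, None] * cum[None, :]
        return mult

    # -- uncertainty -------------------------------------------------------

    def sampled(self, rng: np.random.Generator) -> "Scenario":
        """Draw every declared uncertain parameter and return the perturbed
        scenario.  With no (or all-fixed) distributions this returns an
        equivalent scenario, so a degenerate Monte Carlo run reproduces the
        deterministic pipeline exactly."""
        if not self.uncertainty:
            return self
        draws = {name: sample_parameter(dist, rng)
                 for name, dist in sorted(self.uncertainty.items())}
        scenario = self
        if "delta_mean" in draws:
            table = scenario.exposure.table.copy()
            table["delta_mean"] = np.asarray(draws.pop("delta_mean"), dtype=float)
            scenario = replace(scenario, exposure=ContinuousExposureShift(table))
        if draws and scenario.cost_model:
            params = dict(scenario.cost_model)
            kind = params.pop("kind")
            for name, value in draws.items():
                if name in params:
                    params[name] = float(value)
            if kind == "per_participant":
                costs = _per_participant_stream(**params)
            elif kind == "salt":
                costs = salt_intervention_costs(**params)
            else:
                raise ValueError(f"unknown cost model {kind!r}")
            scenario = replace(scenario, costs=costs)
        return scenario


# ---------------------------------------------------------------------------
# salt reformulation
# ---------------------------------------------------------------------------

def load_food_diary(path: str | os.PathLike) -> pd.DataFrame:
    """Load and validate a food-diary table (one row per person, stratum and
    food group, with grams consumed and baseline/target salt densities)."""
    df = pd.read_csv(path)
    return validate_food_diary(df, file=os.path.basename(os.fspath(path)))


def validate_food_diary(diary: pd.DataFrame, file: str = "<in-memory>") -> pd.DataFrame:
    missing = [c for c in FOOD_DIARY_COLUMNS if c not in diary.columns]
    if missing:
        raise BoundViolationError(f"food diary missing columns {missing}", file=file)
    if len(diary) == 0:
        raise InputValidationError("food diary is empty", file=file)
    for col, desc in (("grams_per_day", "grams"),
                      ("baseline_salt_density", "salt density"),
                      ("target_salt_density", "salt density")):
        if (diary[col] < 0).any():
            raise BoundViolationError(f"{desc} must be >= 0", file=file, column=col)
    if (diary["target_salt_density"] > diary["baseline_salt_density"] + 1e-12).any():
        raise BoundViolationError(
            "reformulation only lowers salt: target density must not exceed baseline",
            file=file, column="target_salt_density")
    return canonical_sort(diary[FOOD_DIARY_COLUMNS])


def _person_salt(diary: pd.DataFrame, density_col: str) -> pd.DataFrame:
    g = diary["grams_per_day"] * diary[density_col] / 100.0
    out = g.groupby([diary[c] for c in STRATUM_COLS + ["person_id"]]).sum()
    return out.rename("salt").reset_index()


def apply_salt_targets(diary: pd.DataFrame) -> ContinuousExposureShift:
    """Reformulate every food group to its target salt density and return the
    per-stratum change in daily salt intake.

    Per person the change is ``sum over food groups of grams x (target -
    baseline density) / 100`` (no other dietary change); per stratum the
    shift is the mean of the person changes and its standard error is the
    person-level standard deviation divided by sqrt(n).
    """
    diary = validate_food_diary(diary)
    delta = (diary["grams_per_day"]
             * (diary["target_salt_density"] - diary["baseline_salt_density"]) / 100.0)
    person = delta.groupby([diary[c] for c in STRATUM_COLS + ["person_id"]]).sum()
    person = person.rename("delta").reset_index()
    grouped = person.groupby(STRATUM_COLS, sort=False)["delta"]
    table = grouped.agg(delta_mean="mean", _sd=lambda s: s.std(ddof=1),
                        _n="count").reset_index()
    if (table["_n"] == 0).any():
        raise InputValidationError("stratum with zero persons in food diary")
    table["se_delta"] = (table["_sd"].fillna(0.0)
                         / np.sqrt(table["_n"])).astype(float)
    table = canonical_sort(table.drop(columns=["_sd", "_n"]))
    return ContinuousExposureShift(table)


def baseline_salt_means(diary: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum mean (and SE) of baseline daily salt intake, g/day."""
    person = _person_salt(validate_food_diary(diary), "baseline_salt_density")
    grouped = person.groupby(STRATUM_COLS, sort=False)["salt"]
    out = grouped.agg(mean_salt="mean", _sd=lambda s: s.std(ddof=1), _n="count").reset_index()
    out["se_salt"] = (out["_sd"].fillna(0.0) / np.sqrt(out["_n"])).astype(float)
    return canonical_sort(out.drop(columns=["_sd", "_n"]))


def annual_monitoring_cost(kantar_annual: float, sodium_survey_cost: float,
                           survey_period_years: int) -> float:
    """Annual government monitoring cost: the purchasing-panel subscription
    plus the sodium survey cost annualised over its period."""
    if survey_period_years < 1:
        raise BoundViolationError("survey_period_years must be >= 1")
    return kantar_annual + sodium_survey_cost / survey_period_years


def salt_intervention_costs(n_products: int = SALT_COST_DEFAULTS["n_products"],
                            cost_per_product: float = SALT_COST_DEFAULTS["cost_per_product"],
                            kantar_annual: float = SALT_COST_DEFAULTS["kantar_annual"],
                            sodium_survey_cost: float = SALT_COST_DEFAULTS["sodium_survey_cost"],
                            survey_period_years: int = SALT_COST_DEFAULTS["survey_period_years"],
                            admin_annual: float = SALT_COST_DEFAULTS["admin_annual"],
                            phase_in: PhaseInSchedule = PhaseInSchedule(),
                            horizon: int = 10) -> CostStream:
    """Payer-tagged cost stream of the salt reformulation intervention.

    Industry bears the one-off reformulation bill (products x unit cost)
    split across years by the phase-in schedule; government bears annual
    monitoring plus administration for every year of the horizon
    (surveillance continues after reformulation completes).
    """
    if min(n_products, cost_per_product, kantar_annual,
           sodium_survey_cost, admin_annual) < 0:
        raise BoundViolationError("cost inputs must be >= 0")
    industry_total = n_products * cost_per_product
    industry = industry_total * phase_in.fraction_in_year(horizon)
    government = np.full(
        horizon,
        annual_monitoring_cost(kantar_annual, sodium_survey_cost, survey_period_years)
        + admin_annual)
    frame = pd.DataFrame({"industry": industry, "government": government},
                         index=range(1, horizon + 1))
    return CostStream(frame)


def build_salt_scenario(diary: pd.DataFrame,
                        phase_in: PhaseInSchedule = PhaseInSchedule(),
                        horizon: int = 10,
                        name: str = "salt_reformulation",
                        age_mask: tuple | None = None,
                        **cost_kwargs) -> Scenario:
    """Salt reformulation scenario from food-diary microdata.

    The exposure shift comes from :func:`apply_salt_targets`; its per-stratum
    standard error feeds a normal effect-size distribution for Monte Carlo
    runs.  Cost inputs default to :data:`SALT_COST_DEFAULTS`.
    """
    params = {**SALT_COST_DEFAULTS, **cost_kwargs}
    shift = apply_salt_targets(diary)
    costs = salt_intervention_costs(phase_in=phase_in, horizon=horizon, **params)
    uncertainty = {
        "delta_mean": ParameterDistribution(
            kind="normal", target="delta_mean",
            params={"mean": shift.table["delta_mean"].to_numpy(),
                    "sd": shift.table["se_delta"].to_numpy()}),
    }
    return Scenario(
        name=name, kind="salt", exposure=shift, phase_in=phase_in, costs=costs,
        age_mask=age_mask, uncertainty=uncertainty,
        cost_model={"kind": "salt", "phase_in": phase_in, "horizon": horizon, **params},
    )


def build_full_salt_reduction_scenario(diary: pd.DataFrame,
                                       horizon: int = 10) -> Scenario:
    """Extreme-value scenario: 100% of dietary salt removed (the shift is
    minus the per-stratum baseline mean intake), with no costs attached."""
    means = baseline_salt_means(diary)
    table = means.rename(columns={"mean_salt": "delta_mean", "se_salt": "se_delta"})
    table["delta_mean"] = -table["delta_mean"]
    shift = ContinuousExposureShift(table[STRATUM_COLS + ["delta_mean", "se_delta"]])
    return Scenario(
        name="salt_reduction_100pct", kind="salt", exposure=shift,
        phase_in=PhaseInSchedule((1.0,)), costs=zero_cost_stream(horizon))


def null_scenario(strata: pd.DataFrame, horizon: int = 10) -> Scenario:
    """A scenario that changes nothing and costs nothing (ill-posed for
    cost-effectiveness comparison; used for null-equivalence checks)."""
    table = strata[STRATUM_COLS].copy()
    table["delta_mean"] = 0.0
    table["se_delta"] = 0.0
    return Scenario(
        name="null", kind="salt", exposure=ContinuousExposureShift(table),
        phase_in=PhaseInSchedule((1.0,)), costs=zero_cost_stream(horizon))


# ---------------------------------------------------------------------------
# leisure-centre access
# ---------------------------------------------------------------------------

def transitions_matrix(transitions: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Coerce a participant transition table (rows: starting category) into
    a 4x4 row-stochastic matrix in canonical category order."""
    if isinstance(transitions, pd.DataFrame):
        t = transitions.set_index("from_category").loc[list(CATEGORIES), list(CATEGORIES)]
        return t.to_numpy(dtype=float)
    return np.asarray(transitions, dtype=float)


def _per_participant_stream(participants: float, cost_y1: float,
                            cost_later: float, horizon: int) -> CostStream:
    gov = np.full(horizon, participants * cost_later)
    gov[0] = participants * cost_y1
    frame = pd.DataFrame({"government": gov}, index=range(1, horizon + 1))
    return CostStream(frame)


def participant_counts(activity_baseline: pd.DataFrame,
                       participation: pd.DataFrame,
                       population: pd.DataFrame,
                       age_mask: tuple | None = None) -> pd.DataFrame:
    """Participants per stratum: population x non-sedentary share x
    participation fraction (participants are never sedentary)."""
    df = population.merge(activity_baseline, on=STRATUM_COLS) \
                   .merge(participation, on=STRATUM_COLS)
    non_sed = 1.0 - df["sedentary"]
    df["participants"] = df["count"] * non_sed * df["participation"]
    if age_mask is not None:
        lo, hi = age_mask
        age = df["age_start"].to_numpy()
        keep = np.ones(len(df), dtype=bool)
        if lo is not None:
            keep &= age + df["age_width"].to_numpy() - 1 >= lo
        if hi is not None:
            keep &= age <= hi
        df.loc[~keep, "participants"] = 0.0
    return df[STRATUM_COLS + ["participants"]]


def build_leisure_scenario(activity_baseline: pd.DataFrame,
                           participation: pd.DataFrame,
                           transitions: pd.DataFrame | np.ndarray,
                           population: pd.DataFrame,
                           cost_y1: float = LEISURE_COST_Y1[1],
                           cost_later: float = LEISURE_COST_LATER[1],
                           horizon: int = 10,
                           age_mask: tuple | None = (16, None),
                           name: str = "leisure_centre_access",
                           cost_uncertainty: bool = True) -> Scenario:
    """Leisure-centre access scenario.

    Participants (the participating share of the non-sedentary population)
    change activity category per the transition matrix; government pays a
    per-participant cost, higher in year one, every year of the horizon.
    Per-participant costs carry triangular uncertainty by default.
    """
    T = transitions_matrix(transitions)
    merged = activity_baseline.merge(participation, on=STRATUM_COLS)
    scen_rows = []
    for _, row in merged.iterrows():
        base = row[list(CATEGORIES)].to_numpy(dtype=float)
        scen = pathways.apply_category_transitions(base, float(row["participation"]), T)
        scen_rows.append(scen)
    scenario_df = merged[STRATUM_COLS].copy()
    scenario_df[list(CATEGORIES)] = np.asarray(scen_rows)
    perturbation = ActivityPerturbation(
        baseline=activity_baseline[STRATUM_COLS + list(CATEGORIES)].copy(),
        scenario=scenario_df)

    participants = float(participant_counts(
        activity_baseline, participation, population, age_mask)["participants"].sum())
    costs = _per_participant_stream(participants, cost_y1, cost_later, horizon)
    uncertainty = {}
    if cost_uncertainty:
        uncertainty = {
            "cost_y1": ParameterDistribution(
                kind="triangular", target="cost_y1",
                params=dict(zip(("low", "mode", "high"), LEISURE_COST_Y1))),
            "cost_later": ParameterDistribution(
                kind="triangular", target="cost_later",
                params=dict(zip(("low", "mode", "high"), LEISURE_COST_LATER))),
        }
    return Scenario(
        name=name, kind="leisure", exposure=perturbation,
        phase_in=PhaseInSchedule((1.0,)), costs=costs, age_mask=age_mask,
        uncertainty=uncertainty,
        cost_model={"kind": "per_participant", "participants": participants,
                    "cost_y1": cost_y1, "cost_later": cost_later, "horizon": horizon},
    )


def build_all_sedentary_scenario(activity_baseline: pd.DataFrame,
                                 horizon: int = 10) -> Scenario:
    """Extreme-value scenario: the whole population becomes sedentary."""
    scen = activity_baseline[STRATUM_COLS].copy()
    scen[list(CATEGORIES)] = 0.0
    scen["sedentary"] = 1.0
    perturbation = ActivityPerturbation(
        baseline=activity_baseline[STRATUM_COLS + list(CATEGORIES)].copy(),
        scenario=scen)
    return Scenario(
        name="all_sedentary", kind="leisure", exposure=perturbation,
        phase_in=PhaseInSchedule((1.0,)), costs=zero_cost_stream(horizon))
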