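"""Discounted health-economic outcomes: QALYs, HALYs, costs, ICER, ROI.

Conventions
-----------
Discounting divides year *t* by ``(1 + rate)^(t - 1)``: the first model
year is undiscounted.  The base-case rate is 1.5%/year, applied to costs
and health outcomes alike.

Writing ``E_b``/``E_a`` for total discounted QALYs with/without the
intervention, ``C_a`` for health and social care expenditure without it,
``C_i`` for the intervention cost and ``C_b = C_i`` + care expenditure with
the intervention:

* cost-effectiveness (ICER) = ``(C_b - C_a) / (E_b - E_a)``;
* the intervention *dominates* doing nothing when ``C_b - C_a < 0`` and
  ``E_b - E_a > 0``, and is *dominated* when it costs more and gains
  nothing;
* return on investment, reported when the intervention is cost saving, is
  ``(NHS savings + social care savings) / C_i`` — pounds returned per pound
  spent.  The signed net form ``(C_b - C_a)/C_i = 1 - ROI`` is exposed as
  ``roi_net``; the two conventions disagree in sign and both are reported.

Social care costs are a function of age and quality of life:
``12 x base monthly cost x eligibility(age) x (1 + sensitivity x (1 - mean
utility))`` per person-year, plus age-related costs unrelated to the
modelled diseases.  NHS costs are the per-prevalent-case annual disease
costs plus unrelated background costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epidata import ModelInputs, UndefinedComparisonError, _SEX_ORDER
from .lifetable import Trajectory, _AgeLookup, run_cohort

__all__ = [
    "DiscountSpec",
    "EconomicSummary",
    "CEResult",
    "ScenarioResult",
    "discount_stream",
    "qalys",
    "halys",
    "care_costs",
    "cost_effectiveness",
    "return_on_investment",
    "time_to_cost_saving",
    "intervention_budget_for_icer",
    "evaluate_scenario",
    "summary_by_sex",
]

PERSPECTIVES = ("health_and_social", "nhs_only", "social_only")


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate; year 1 is undiscounted, year t is divided by
    (1 + rate)^(t-1)."""

    rate: float = 0.015

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("discount rate must be >= 0")

    def factors(self, horizon: int) -> np.ndarray:
        return (1.0 + self.rate) ** -np.arange(horizon)


def discount_stream(values, spec: DiscountSpec) -> float:
    """Discounted total of a per-year stream (year 1 undiscounted)."""
    values = np.asarray(values, dtype=float)
    return float(values @ spec.factors(len(values)))


# ---------------------------------------------------------------------------
# health outcomes
# ---------------------------------------------------------------------------

def qaly_stream(traj: Trajectory, mask: np.ndarray | None = None) -> np.ndarray:
    """Undiscounted QALYs per model year: person-years x mean utility."""
    w = traj.person_years * traj.mean_utility
    if mask is not None:
        w = w[mask]
    return w.sum(axis=0)


def qalys(traj: Trajectory, spec: DiscountSpec,
          mask: np.ndarray | None = None) -> float:
    """Total discounted quality-adjusted life years of one arm."""
    return discount_stream(qaly_stream(traj, mask), spec)


def halys(traj: Trajectory, inputs: ModelInputs, spec: DiscountSpec,
          disability_per_prevalent_case: dict[str, float] | None = None,
          background_disability: pd.DataFrame | None = None) -> float:
    """Total discounted health-adjusted life years.

    Person-years are weighted by ``1 - background disability - sum over
    diseases of prevalence x disability weight`` (floored at 0).  Disability
    weights default to the registry's per-prevalent-case values and the
    background to the utilities table; passing the utility decrements as
    weights and ``1 - baseline utility`` as background makes HALYs equal
    QALYs by construction.
    """
    si = inputs.single_year()
    if disability_per_prevalent_case is None:
        disability_per_prevalent_case = dict(
            zip(si.registry["disease"], si.registry["disability_per_prevalent_case"]))
    bg_table = background_disability if background_disability is not None else si.utilities
    bg_col = "background_disability" if "background_disability" in bg_table.columns \
        else bg_table.columns[-1]
    bg = _AgeLookup(bg_table, bg_col)

    sex_idx = traj.strata["sex"].map(_SEX_ORDER).to_numpy()
    age0 = traj.strata["age_start"].to_numpy(dtype=int)
    total = np.zeros(traj.n_years)
    for t in range(traj.n_years):
        weight = 1.0 - bg.at(sex_idx, age0 + t)
        for d in traj.diseases:
            weight = weight - traj.disease_states[d].prevalence[:, t] \
                * disability_per_prevalent_case.get(d, 0.0)
        total[t] = float(traj.person_years[:, t] @ np.maximum(weight, 0.0))
    return discount_stream(total, spec)


# ---------------------------------------------------------------------------
# care costs
# ---------------------------------------------------------------------------

@dataclass
class CareCosts:
    """Per-year NHS and social-care expenditure for one arm."""

    nhs_stream: np.ndarray     # (T,) undiscounted
    social_stream: np.ndarray  # (T,) undiscounted
    spec: DiscountSpec

    @property
    def nhs_total(self) -> float:
        return discount_stream(self.nhs_stream, self.spec)

    @property
    def social_total(self) -> float:
        return discount_stream(self.social_stream, self.spec)

    def total(self, perspective: str = "health_and_social") -> float:
        if perspective == "nhs_only":
            return self.nhs_total
        if perspective == "social_only":
            return self.social_total
        return self.nhs_total + self.social_total

    def stream(self, perspective: str = "health_and_social") -> np.ndarray:
        if perspective == "nhs_only":
            return self.nhs_stream
        if perspective == "social_only":
            return self.social_stream
        return self.nhs_stream + self.social_stream


def care_costs(traj: Trajectory, inputs: ModelInputs, spec: DiscountSpec,
               mask: np.ndarray | None = None) -> CareCosts:
    """NHS and social-care expenditure streams implied by a trajectory.

    NHS: per-disease annual cost per prevalent case (by current age and
    sex) times prevalent person-years, plus unrelated background NHS costs.
    Social care: the age-eligibility x utility-sensitive monthly cost model
    plus unrelated background social costs.
    """
    si = inputs.single_year()
    sex_idx = traj.strata["sex"].map(_SEX_ORDER).to_numpy()
    age0 = traj.strata["age_start"].to_numpy(dtype=int)
    S = len(traj.strata)
    sel = np.ones(S, dtype=bool) if mask is None else mask

    cost_lu = {
        d: _AgeLookup(sub, "nhs_annual_cost_per_prevalent_case")
        for d, sub in si.disease_epi.groupby("disease", sort=False)
    }
    unrel_nhs = _AgeLookup(si.utilities, "unrelated_nhs_cost")
    unrel_soc = _AgeLookup(si.utilities, "unrelated_social_cost")
    elig = _AgeLookup(si.social_care, "eligibility")
    base_monthly = float(si.social_care["base_monthly_cost"].iloc[0])
    sensitivity = float(si.social_care["utility_sensitivity"].iloc[0])

    T = traj.n_years
    nhs = np.zeros(T)
    social = np.zeros(T)
    for t in range(T):
        age = age0 + t
        py = traj.person_years[:, t]
        per_person_nhs = unrel_nhs.at(sex_idx, age)
        disease_cost = np.zeros(S)
        for d in traj.diseases:
            disease_cost += traj.disease_states[d].prevalence[:, t] \
                * cost_lu[d].at(sex_idx, age)
        soc_rate = 12.0 * base_monthly * elig.at(sex_idx, age) \
            * (1.0 + sensitivity * (1.0 - traj.mean_utility[:, t])) \
            + unrel_soc.at(sex_idx, age)
        nhs[t] = float((py * (per_person_nhs + disease_cost))[sel].sum())
        social[t] = float((py * soc_rate)[sel].sum())
    return CareCosts(nhs_stream=nhs, social_stream=social, spec=spec)


# ---------------------------------------------------------------------------
# summaries and decision measures
# ---------------------------------------------------------------------------

@dataclass
class EconomicSummary:
    """Discounted economics of one scenario-vs-baseline comparison."""

    e_a: float  # QALYs without the intervention
    e_b: float  # QALYs with the intervention
    c_a: float  # care expenditure without the intervention
    c_b: float  # intervention cost + care expenditure with it
    c_i: float  # intervention cost
    nhs_saving: float
    social_saving: float
    industry_cost: float
    government_cost: float
    horizon: int
    discount_rate: float
    perspective: str = "health_and_social"
    # per-year streams (undiscounted unless suffixed)
    streams: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def delta_qalys(self) -> float:
        return self.e_b - self.e_a

    @property
    def delta_cost(self) -> float:
        return self.c_b - self.c_a

    def validate(self, rtol: float = 1e-6) -> None:
        checks = [
            (self.c_i, self.industry_cost + self.government_cost),
            (self.delta_cost, self.c_i - self.nhs_saving - self.social_saving),
        ]
        for got, want in checks:
            scale = max(abs(got), abs(want), 1.0)
            if abs(got - want) > rtol * scale:
                raise AssertionError(
                    f"economic components do not sum: {got} != {want}")


@dataclass
class CEResult:
    """Cost-effectiveness classification of a scenario against doing
    nothing: dominant (saves money, gains health), dominated (costs money,
    gains nothing), or an ICER."""

    classification: str  # "dominant" | "dominated" | "icer"
    icer: float | None = None
    roi: float | None = None
    roi_net: float | None = None
    years_to_cost_saving: int | None = None


def return_on_investment(nhs_saving: float, social_saving: float,
                         c_i: float) -> tuple[float, float]:
    """Pounds returned (NHS + social care savings) per pound of intervention
    spend, together with the signed net convention ``(C_b - C_a)/C_i =
    1 - ROI``."""
    if c_i <= 0:
        raise ZeroDivisionError("return on investment undefined for zero intervention cost")
    roi = (nhs_saving + social_saving) / c_i
    return roi, 1.0 - roi


def cost_effectiveness(summary: EconomicSummary) -> CEResult:
    """Classify a comparison and compute its ICER / ROI."""
    d_cost = summary.delta_cost
    d_qaly = summary.delta_qalys
    if d_cost == 0.0 and d_qaly == 0.0:
        raise UndefinedComparisonError(
            "scenario is indistinguishable from doing nothing "
            "(zero cost difference and zero QALY difference)")
    roi = roi_net = None
    if d_cost < 0 and summary.c_i > 0:
        roi, roi_net = return_on_investment(
            summary.nhs_saving, summary.social_saving, summary.c_i)
    if d_cost < 0 and d_qaly > 0:
        return CEResult(classification="dominant", roi=roi, roi_net=roi_net)
    if d_qaly <= 0 and d_cost >= 0:
        return CEResult(classification="dominated")
    return CEResult(classification="icer", icer=d_cost / d_qaly,
                    roi=roi, roi_net=roi_net)


def time_to_cost_saving(savings_per_year, intervention_cost_per_year) -> int | None:
    """First year in which cumulative (discounted) savings reach cumulative
    intervention costs; ``None`` if they never do within the streams."""
    s = np.cumsum(np.asarray(savings_per_year, dtype=float))
    c = np.cumsum(np.asarray(intervention_cost_per_year, dtype=float))
    hit = np.flatnonzero(s >= c)
    return int(hit[0]) + 1 if len(hit) else None


def intervention_budget_for_icer(target_icer: float, delta_qalys: float,
                                 nhs_saving: float, social_saving: float) -> float:
    """Intervention budget at which the cost per QALY equals a target
    threshold: budget = target x delta QALYs + care savings."""
    return target_icer * delta_qalys + nhs_saving + social_saving


# ---------------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    summary: EconomicSummary
    ce: CEResult
    baseline_traj: Trajectory
    scenario_traj: Trajectory


def evaluate_scenario(inputs: ModelInputs, scenario,
                      horizon: int | None = 10,
                      discount: DiscountSpec = DiscountSpec(),
                      include_industry_costs: bool = True,
                      perspective: str = "health_and_social",
                      baseline: Trajectory | None = None) -> ScenarioResult:
    """Run both arms and produce the full economic comparison.

    ``horizon=None`` uses a lifetime horizon.  ``baseline`` may carry a
    precomputed baseline trajectory (the baseline arm does not depend on the
    scenario, so Monte Carlo runs compute it once).
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"perspective must be one of {PERSPECTIVES}")
    if baseline is None:
        baseline = run_cohort(inputs, None, horizon)
    T = baseline.n_years
    multipliers = scenario.incidence_multipliers(inputs, T)
    scen_traj = run_cohort(inputs, multipliers, T)

    e_a = qalys(baseline, discount)
    e_b = qalys(scen_traj, discount)
    care_a = care_costs(baseline, inputs, discount)
    care_b = care_costs(scen_traj, inputs, discount)

    cost_frame = scenario.costs.extended(T).frame
    payers = ["government"] + (["industry"] if include_industry_costs else [])
    ci_stream = cost_frame[payers].sum(axis=1).to_numpy()
    factors = discount.factors(T)
    c_i = float(ci_stream @ factors)
    industry_cost = float(cost_frame["industry"].to_numpy() @ factors) \
        if include_industry_costs else 0.0
    government_cost = float(cost_frame["government"].to_numpy() @ factors)

    nhs_saving = care_a.nhs_total - care_b.nhs_total
    social_saving = care_a.social_total - care_b.social_total
    c_a = care_a.total(perspective)
    c_b = c_i + care_b.total(perspective)
    if perspective == "nhs_only":
        social_saving_eff = 0.0
        nhs_saving_eff = nhs_saving
    elif perspective == "social_only":
        social_saving_eff = social_saving
        nhs_saving_eff = 0.0
    else:
        nhs_saving_eff, social_saving_eff = nhs_saving, social_saving

    summary = EconomicSummary(
        e_a=e_a, e_b=e_b, c_a=c_a, c_b=c_b, c_i=c_i,
        nhs_saving=nhs_saving_eff, social_saving=social_saving_eff,
        industry_cost=industry_cost, government_cost=government_cost,
        horizon=T, discount_rate=discount.rate, perspective=perspective,
        streams={
            "intervention_cost": ci_stream,
            "nhs_saving": care_a.nhs_stream - care_b.nhs_stream,
            "social_saving": care_a.social_stream - care_b.social_stream,
            "qalys_baseline": qaly_stream(baseline),
            "qalys_scenario": qaly_stream(scen_traj),
        },
    )
    summary.validate()
    ce = cost_effectiveness(summary)
    savings_stream = summary.streams["nhs_saving"] * (perspective != "social_only") \
        + summary.streams["social_saving"] * (perspective != "nhs_only")
    ce.years_to_cost_saving = time_to_cost_saving(
        savings_stream * factors, ci_stream * factors)
    return ScenarioResult(summary=summary, ce=ce,
                          baseline_traj=baseline, scenario_traj=scen_traj)


def summary_by_sex(result: ScenarioResult, inputs: ModelInputs,
                   discount: DiscountSpec = DiscountSpec()) -> pd.DataFrame:
    """Table-style breakdown by sex: QALY change, NHS and social-care
    savings (intervention costs cannot be attributed to one sex)."""
    rows = []
    for sex in ("male", "female"):
        mask = result.baseline_traj.sex_mask(sex)
        d_q = qalys(result.scenario_traj, discount, mask) \
            - qalys(result.baseline_traj, discount, mask)
        ca = care_costs(result.baseline_traj, inputs, discount, mask)
        cb = care_costs(result.scenario_traj, inputs, discount, mask)
        rows.append({
            "group": sex,
            "delta_qalys": d_q,
            "nhs_saving": ca.nhs_total - cb.nhs_total,
            "social_saving": ca.social_total - cb.social_total,
            "intervention_cost": np.nan,
        })
    rows.append({
        "group": "total",
        "delta_qalys": result.summary.delta_qalys,
        "nhs_saving": result.summary.nhs_saving,
        "social_saving": result.summary.social_saving,
        "intervention_cost": result.summary.c_i,
    })
    return pd.DataFrame(rows)
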