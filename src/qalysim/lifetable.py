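"""The multistate life table engine.

A closed adult cohort is propagated through annual cycles.  Each (sex,
single year of age) stratum carries, alongside its survivorship, one
prevalence state per modelled disease.  Within a cycle the updates are
ordered: incidence -> disease deaths -> remission -> other-cause deaths,
with other-cause (residual) deaths removed proportionally from the diseased
and disease-free pools while disease deaths come out of the diseased pool
only.  Diseases are independent of one another (no comorbidity
interaction).

Rates are annual risks.  For disease *d* in a stratum with survivors ``N``
and start-of-cycle prevalence ``p``::

    new cases       = N * (1 - p) * incidence
    disease deaths  = N * p * case_fatality
    remitted        = N * p * remission
    p(next)         = (N*p + new - disease deaths - remitted) / (N - disease deaths)

(the proportional removal of all other deaths cancels from numerator and
denominator, so the residual rate does not appear in the prevalence
update).  Total deaths in the cycle are the evolving disease deaths plus a
residual (other-cause) mortality schedule fixed by the input tables —
all-cause mortality minus the disease deaths implied by the *table*
prevalences — so an intervention that lowers disease prevalence averts
deaths rather than reshuffling them.  Person-years use a half-cycle
correction.

Cohorts older than the oldest age in the input tables keep using that
oldest age's rates (open-ended terminal band) and are followed to age 110
or until survivorship falls below 1e-9 of the initial cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epidata import (
    AGE_FOLLOWUP_CAP,
    SURVIVOR_FLOOR,
    STRATUM_COLS,
    _SEX_ORDER,
    ModelInputs,
)

logger = logging.getLogger("qalysim")

__all__ = [
    "DiseaseStateTrajectory",
    "Trajectory",
    "disease_process",
    "residual_mortality",
    "run_cohort",
]


# ---------------------------------------------------------------------------
# elementary processes
# ---------------------------------------------------------------------------

def disease_process(incidence, case_fatality, remission, prevalence, survivors):
    """One annual update of a single disease state.

    Returns ``(prevalence_next, incident_cases, disease_deaths)``.  Inputs
    may be scalars or aligned arrays.  The next-cycle prevalence is clamped
    to [0, 1]; clamping is logged because it signals inconsistent rates.
    """
    incidence = np.asarray(incidence, dtype=float)
    case_fatality = np.asarray(case_fatality, dtype=float)
    remission = np.asarray(remission, dtype=float)
    prevalence = np.asarray(prevalence, dtype=float)
    survivors = np.asarray(survivors, dtype=float)
    for name, rate in (("incidence", incidence), ("case_fatality", case_fatality),
                       ("remission", remission), ("prevalence", prevalence)):
        if (rate < 0).any():
            raise ValueError(f"negative {name} rate")

    new_cases = survivors * (1.0 - prevalence) * incidence
    disease_deaths = survivors * prevalence * case_fatality
    remitted = survivors * prevalence * remission
    denom = survivors - disease_deaths
    with np.errstate(invalid="ignore", divide="ignore"):
        prev_next = np.where(
            denom > 0.0,
            (survivors * prevalence + new_cases - disease_deaths - remitted)
            / np.where(denom > 0.0, denom, 1.0),
            0.0,
        )
    if (prev_next < 0.0).any() or (prev_next > 1.0).any():
        logger.warning("disease prevalence clamped to [0, 1] during update")
        prev_next = np.clip(prev_next, 0.0, 1.0)
    return prev_next, new_cases, disease_deaths


def residual_mortality(all_cause, disease_death_rates):
    """Other-cause mortality: the all-cause rate minus the modelled
    disease-death rates (sum over diseases of prevalence x case fatality),
    floored at zero with a logged warning."""
    all_cause = np.asarray(all_cause, dtype=float)
    total = np.zeros_like(all_cause)
    for rate in disease_death_rates:
        total = total + np.asarray(rate, dtype=float)
    residual = all_cause - total
    if (residual < 0).any():
        logger.warning(
            "modelled disease deaths exceed all-cause mortality in %d strata; "
            "residual mortality floored at 0", int((residual < 0).sum()))
        residual = np.maximum(residual, 0.0)
    return residual


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class DiseaseStateTrajectory:
    """Per-cycle disease state for one disease across all strata."""

    prevalence: np.ndarray      # (S, T) start-of-cycle prevalence
    incident_cases: np.ndarray  # (S, T) persons
    disease_deaths: np.ndarray  # (S, T) persons


@dataclass
class Trajectory:
    """Year-by-year cohort accounts for one arm (baseline or scenario)."""

    strata: pd.DataFrame          # sex, age_start (single-year), age_width
    initial: np.ndarray           # (S,) starting cohort
    alive_start: np.ndarray       # (S, T)
    deaths: np.ndarray            # (S, T)
    person_years: np.ndarray      # (S, T)
    mean_utility: np.ndarray      # (S, T)
    diseases: list[str]
    disease_states: dict[str, DiseaseStateTrajectory]

    @property
    def n_years(self) -> int:
        return self.alive_start.shape[1]

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, self.n_years + 1)

    def sex_mask(self, sex: str) -> np.ndarray:
        return (self.strata["sex"] == sex).to_numpy()

    def cumulative_incident_cases(self, disease: str) -> float:
        return float(self.disease_states[disease].incident_cases.sum())

    def total_person_years(self) -> float:
        return float(self.person_years.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per stratum and year, with per-disease
        prevalence / incident case / death columns appended."""
        S, T = self.alive_start.shape
        base = self.strata.loc[self.strata.index.repeat(T)].reset_index(drop=True)
        base["year"] = np.tile(np.arange(1, T + 1), S)
        base["alive"] = self.alive_start.ravel()
        base["deaths"] = self.deaths.ravel()
        base["person_years"] = self.person_years.ravel()
        base["mean_utility"] = self.mean_utility.ravel()
        for d in self.diseases:
            st = self.disease_states[d]
            base[f"{d}_prevalence"] = st.prevalence.ravel()
            base[f"{d}_incident_cases"] = st.incident_cases.ravel()
            base[f"{d}_deaths"] = st.disease_deaths.ravel()
        return base


# ---------------------------------------------------------------------------
# cohort engine
# ---------------------------------------------------------------------------

class _AgeLookup:
    """Fast (sex, age) -> value lookup built from a single-year table, with
    ages clamped into the table's range (open-ended terminal band)."""

    def __init__(self, df: pd.DataFrame, col: str):
        self.age_min = int(df["age_start"].min())
        self.age_max = int(df["age_start"].max())
        n_ages = self.age_max - self.age_min + 1
        arr = np.full((2, n_ages), np.nan)
        sex_idx = df["sex"].map(_SEX_ORDER).to_numpy()
        arr[sex_idx, df["age_start"].to_numpy() - self.age_min] = df[col].to_numpy(dtype=float)
        self.values = arr

    def at(self, sex_idx: np.ndarray, age: np.ndarray) -> np.ndarray:
        idx = np.clip(age, self.age_min, self.age_max) - self.age_min
        return self.values[sex_idx, idx]


def _as_multiplier_array(mult, n_strata: int, horizon: int) -> np.ndarray:
    arr = np.asarray(mult, dtype=float)
    if arr.ndim == 0:
        arr = np.full((n_strata, horizon), float(arr))
    elif arr.ndim == 1:
        arr = np.repeat(arr[:, None], horizon, axis=1)
    if arr.shape != (n_strata, horizon):
        raise ValueError(
            f"multiplier table has shape {arr.shape}, expected {(n_strata, horizon)}")
    if (arr <= 0).any():
        raise ValueError("incidence multipliers must be > 0")
    return arr


def run_cohort(inputs: ModelInputs,
               incidence_multipliers: dict[str, np.ndarray] | None = None,
               horizon: int | None = 10) -> Trajectory:
    """Propagate the closed cohort for ``horizon`` annual cycles.

    ``incidence_multipliers`` maps disease name to a scalar, an (S,) array,
    or an (S, T) array of rate ratios applied to that disease's incidence
    (S = number of single-year strata in canonical order).  ``horizon=None``
    runs a lifetime horizon: cycles continue until every stratum's
    survivorship falls below 1e-9 of its initial cohort or the oldest
    cohort reaches age 110.
    """
    si = inputs.single_year()
    pop = si.population
    strata = pop[STRATUM_COLS].reset_index(drop=True)
    S = len(strata)
    sex_idx = strata["sex"].map(_SEX_ORDER).to_numpy()
    age0 = strata["age_start"].to_numpy(dtype=int)

    lifetime = horizon is None
    if lifetime:
        T_max = AGE_FOLLOWUP_CAP - int(age0.min())
    else:
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        T_max = int(horizon)

    mort = _AgeLookup(si.mortality, "all_cause_mortality")
    util = _AgeLookup(si.utilities, "baseline_utility")

    diseases = si.diseases
    epi_by_disease = dict(tuple(si.disease_epi.groupby("disease", sort=False)))
    inc_lu, cf_lu, rem_lu, prev_lu = {}, {}, {}, {}
    decrement = {}
    for d in diseases:
        sub = epi_by_disease[d]
        inc_lu[d] = _AgeLookup(sub, "incidence")
        cf_lu[d] = _AgeLookup(sub, "case_fatality")
        rem_lu[d] = _AgeLookup(sub, "remission")
        prev_lu[d] = _AgeLookup(sub, "prevalence")
        decrement[d] = float(
            si.registry.loc[si.registry["disease"] == d, "utility_decrement"].iloc[0])

    mult = {}
    if incidence_multipliers:
        for d, m in incidence_multipliers.items():
            if d not in diseases:
                raise ValueError(f"multiplier given for unknown disease {d!r}")
            mult[d] = _as_multiplier_array(m, S, T_max)

    N0 = pop["count"].to_numpy(dtype=float)
    N = N0.copy()
    prev = {d: prev_lu[d].at(sex_idx, age0) for d in diseases}

    alive, deaths_a, py_a, mu_a = [], [], [], []
    d_prev = {d: [] for d in diseases}
    d_new = {d: [] for d in diseases}
    d_dead = {d: [] for d in diseases}

    floored = 0
    for t in range(T_max):
        age = age0 + t
        m_t = mort.at(sex_idx, age)
        u_t = util.at(sex_idx, age)

        # residual (other-cause) mortality is a fixed age/sex schedule:
        # all-cause minus the disease deaths implied by the *input-table*
        # prevalences, so that a scenario lowering disease prevalence
        # genuinely averts deaths
        dd_rate_table = np.zeros(S)
        dd_rate = np.zeros(S)
        decr = np.zeros(S)
        for d in diseases:
            cf_t = cf_lu[d].at(sex_idx, age)
            dd_rate_table += prev_lu[d].at(sex_idx, age) * cf_t
            dd_rate += prev[d] * cf_t
            decr += prev[d] * decrement[d]
        resid = m_t - dd_rate_table
        floored += int((resid < 0).sum())
        resid = np.maximum(resid, 0.0)
        death_rate = np.clip(dd_rate + resid, 0.0, 1.0)

        deaths = N * death_rate
        py = N - deaths / 2.0
        mean_u = np.clip(u_t - decr, 0.0, 1.0)

        alive.append(N.copy())
        deaths_a.append(deaths)
        py_a.append(py)
        mu_a.append(mean_u)

        next_prev = {}
        for d in diseases:
            inc = inc_lu[d].at(sex_idx, age)
            if d in mult:
                inc = inc * mult[d][:, t]
            p_next, new_cases, d_deaths = disease_process(
                inc, cf_lu[d].at(sex_idx, age), rem_lu[d].at(sex_idx, age), prev[d], N)
            d_prev[d].append(prev[d].copy())
            d_new[d].append(new_cases)
            d_dead[d].append(d_deaths)
            next_prev[d] = p_next
        prev = next_prev

        N = N - deaths
        if lifetime and (N <= SURVIVOR_FLOOR * np.maximum(N0, 1.0)).all():
            break

    if floored:
        logger.warning(
            "residual mortality floored at 0 in %d stratum-cycles", floored)

    states = {
        d: DiseaseStateTrajectory(
            prevalence=np.column_stack(d_prev[d]),
            incident_cases=np.column_stack(d_new[d]),
            disease_deaths=np.column_stack(d_dead[d]),
        )
        for d in diseases
    }
    return Trajectory(
        strata=strata,
        initial=N0,
        alive_start=np.column_stack(alive),
        deaths=np.column_stack(deaths_a),
        person_years=np.column_stack(py_a),
        mean_utility=np.column_stack(mu_a),
        diseases=diseases,
        disease_states=states,
    )
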