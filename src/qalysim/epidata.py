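"""Stratified model inputs: schemas, loaders, writers and validation.

Every input to the simulator is an age/sex-stratified table.  The stratum
columns ``sex`` ("male"/"female"), ``age_start`` and ``age_width`` (1 or 5
years) index all tables; tables within one bundle must cover identical
strata.  Inputs arrive in 5-year bands and are expanded to single years of
age before the cohort is simulated (piecewise-constant rates, population
counts split evenly across a band).

CSV dialect is fixed so that a load/write cycle is byte-identical:
comma-separated, UTF-8, dot decimal, mandatory header row, canonical row
order (disease, then male before female, then ascending age).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("qalysim")

SEXES = ("male", "female")
_SEX_ORDER = {"male": 0, "female": 1}

#: Activity categories, from least to most active.
CATEGORIES = ("sedentary", "under_active", "active", "recommended")

#: Youngest adult age in the cohort.
AGE_MIN = 15
#: Cohorts are followed no further than this age in lifetime mode.
AGE_FOLLOWUP_CAP = 110
#: A stratum is considered extinct once survivorship falls below this
#: fraction of its initial cohort.
SURVIVOR_FLOOR = 1e-9

#: Diseases every registry must carry.
CORE_DISEASES = (
    "ihd",
    "stroke",
    "type2_diabetes",
    "breast_cancer",
    "colorectal_cancer",
)
#: Full supported disease list: the core five plus the remaining cancer
#: subtypes and liver cirrhosis.
ALL_DISEASES = CORE_DISEASES + (
    "lung_cancer",
    "stomach_cancer",
    "liver_cancer",
    "kidney_cancer",
    "pancreatic_cancer",
    "liver_cirrhosis",
)

STRATUM_COLS = ["sex", "age_start", "age_width"]

SCHEMA_VERSION = "1"

#: Column schema per input file.  Order is the canonical write order.
SCHEMAS: dict[str, list[str]] = {
    "population.csv": STRATUM_COLS + ["count"],
    "mortality.csv": STRATUM_COLS + ["all_cause_mortality"],
    "disease_epi.csv": ["disease"] + STRATUM_COLS + [
        "incidence",
        "prevalence",
        "case_fatality",
        "remission",
        "nhs_annual_cost_per_prevalent_case",
    ],
    "disease_registry.csv": [
        "disease",
        "affected_by",
        "utility_decrement",
        "disability_per_prevalent_case",
    ],
    "utilities.csv": STRATUM_COLS + [
        "baseline_utility",
        "background_disability",
        "unrelated_nhs_cost",
        "unrelated_social_cost",
    ],
    "social_care.csv": STRATUM_COLS + [
        "eligibility",
        "base_monthly_cost",
        "utility_sensitivity",
    ],
    # pathway parameter tables (optional members of a bundle)
    "salt_sbp_model.csv": STRATUM_COLS + ["mmhg_per_gram"],
    "bp_disease_rr.csv": ["disease"] + STRATUM_COLS + ["rr_per_mmhg"],
    "pa_rr.csv": ["disease"] + list(CATEGORIES),
    "pa_baseline.csv": STRATUM_COLS + list(CATEGORIES),
    "pa_participation.csv": STRATUM_COLS + ["participation"],
    "pa_transitions.csv": ["from_category"] + list(CATEGORIES),
}

CORE_FILES = (
    "population.csv",
    "mortality.csv",
    "disease_epi.csv",
    "disease_registry.csv",
    "utilities.csv",
    "social_care.csv",
)
PATHWAY_FILES = ("salt_sbp_model.csv", "bp_disease_rr.csv", "pa_rr.csv")

# columns constrained to [0, 1]
_UNIT_INTERVAL_COLS = {
    "all_cause_mortality",
    "incidence",
    "prevalence",
    "case_fatality",
    "remission",
    "utility_decrement",
    "disability_per_prevalent_case",
    "baseline_utility",
    "background_disability",
    "eligibility",
    "participation",
    "sedentary",
    "under_active",
    "active",
    "recommended",
}
# columns constrained to be non-negative
_NON_NEGATIVE_COLS = {
    "count",
    "nhs_annual_cost_per_prevalent_case",
    "unrelated_nhs_cost",
    "unrelated_social_cost",
    "base_monthly_cost",
    "utility_sensitivity",
    "mmhg_per_gram",
}
# columns constrained to be strictly positive
_POSITIVE_COLS = {"rr_per_mmhg"}
# per-file overrides: in pa_rr.csv the category columns hold relative risks
# (> 0), not proportions
_BOUND_OVERRIDES: dict[str, dict[str, str]] = {
    "pa_rr.csv": {c: "positive" for c in CATEGORIES},
}


# ---------------------------------------------------------------------------
# validation failures
# ---------------------------------------------------------------------------

class InputValidationError(ValueError):
    """Base class for input validation failures, carrying file/row/column."""

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, column: str | None = None):
        self.file = file
        self.row = row
        self.column = column
        ctx = []
        if file is not None:
            ctx.append(f"file={file}")
        if row is not None:
            ctx.append(f"row={row}")
        if column is not None:
            ctx.append(f"column={column}")
        if ctx:
            message = f"{message} [{', '.join(ctx)}]"
        super().__init__(message)


class MissingColumnError(InputValidationError):
    """A required column is absent from an input file."""


class NonNumericCellError(InputValidationError):
    """A cell that must be numeric failed to parse."""


class BoundViolationError(InputValidationError):
    """A value lies outside its declared bounds."""


class StratumMismatchError(InputValidationError):
    """Two tables of one bundle do not cover identical strata."""


class BandContiguityError(InputValidationError):
    """Age bands overlap or leave a gap."""


class UndefinedComparisonError(ValueError):
    """Cost-effectiveness comparison of two identical arms (null scenario)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Stratum:
    """One (age band, sex) cell of the closed cohort."""

    sex: str
    age_start: int
    age_width: int = 5

    def __post_init__(self):
        if self.sex not in SEXES:
            raise BoundViolationError(f"unknown sex {self.sex!r}")
        if self.age_start < 0:
            raise BoundViolationError(f"age_start must be >= 0, got {self.age_start}")
        if self.age_width not in (1, 5):
            raise BoundViolationError(f"age_width must be 1 or 5, got {self.age_width}")


@dataclass
class ConsistencyReport:
    """Per-stratum check that modelled disease deaths fit under all-cause
    mortality, i.e. sum over diseases of prevalence x case fatality never
    exceeds the all-cause rate (required for a non-negative residual)."""

    frame: pd.DataFrame  # sex, age_start, age_width, disease_death_rate, all_cause_mortality, ok
    violations: list[Stratum]

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class ModelInputs:
    """Validated bundle of stratified input tables, all on identical strata."""

    population: pd.DataFrame
    mortality: pd.DataFrame
    disease_epi: pd.DataFrame
    registry: pd.DataFrame
    utilities: pd.DataFrame
    social_care: pd.DataFrame
    salt_sbp: pd.DataFrame | None = None
    bp_rr: pd.DataFrame | None = None
    pa_rr: pd.DataFrame | None = None
    schema_version: str = SCHEMA_VERSION
    _single_year_cache: "ModelInputs | None" = field(
        default=None, repr=False, compare=False)

    @property
    def diseases(self) -> list[str]:
        return list(self.registry["disease"])

    @property
    def strata(self) -> pd.DataFrame:
        return self.population[STRATUM_COLS].copy()

    @property
    def age_width(self) -> int:
        return int(self.population["age_width"].iloc[0])

    def single_year(self) -> "ModelInputs":
        """Return the bundle expanded to single years of age (cached)."""
        if self.age_width == 1:
            return self
        if self._single_year_cache is None:
            expanded = ModelInputs(
                population=expand_age_bands(self.population, count_cols=("count",)),
                mortality=expand_age_bands(self.mortality),
                disease_epi=expand_age_bands(self.disease_epi),
                registry=self.registry.copy(),
                utilities=expand_age_bands(self.utilities),
                social_care=expand_age_bands(self.social_care),
                salt_sbp=None if self.salt_sbp is None else expand_age_bands(self.salt_sbp),
                bp_rr=None if self.bp_rr is None else expand_age_bands(self.bp_rr),
                pa_rr=None if self.pa_rr is None else self.pa_rr.copy(),
                schema_version=self.schema_version,
            )
            self._single_year_cache = expanded
        return self._single_year_cache


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sort_key_frame(df: pd.DataFrame) -> pd.DataFrame:
    key = df.copy()
    if "sex" in key.columns:
        key["_sex_order"] = key["sex"].map(_SEX_ORDER)
    return key


def canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Sort a stratified table into canonical order: leading id columns
    (disease, person, food group) alphabetically, male before female,
    ascending age."""
    cols = []
    for c in ("disease", "person_id", "food_group", "from_category"):
        if c in df.columns:
            cols.append(c)
    key = _sort_key_frame(df)
    sort_cols = cols + [c for c in ("_sex_order", "age_start") if c in key.columns]
    if not sort_cols:
        return df.reset_index(drop=True)
    out = key.sort_values(sort_cols, kind="mergesort").drop(columns="_sex_order", errors="ignore")
    return out.reset_index(drop=True)


def _coerce_numeric(df: pd.DataFrame, col: str, fname: str) -> pd.Series:
    # parse with Python's correctly-rounded float() so that a load/write
    # cycle is bit-exact (pandas' fast parser can be off by one ulp)
    raw = df[col].to_numpy()
    out = np.empty(len(raw))
    for row, cell in enumerate(raw):
        try:
            out[row] = float(cell)
        except (TypeError, ValueError):
            raise NonNumericCellError(
                f"cell {cell!r} is not numeric",
                file=fname, row=row, column=col) from None
    return pd.Series(out, index=df.index)


def _check_bounds(df: pd.DataFrame, fname: str) -> None:
    overrides = _BOUND_OVERRIDES.get(fname, {})
    for col in df.columns:
        lo, hi, strict = None, None, False
        if overrides.get(col) == "positive":
            lo, strict = 0.0, True
        elif col in _UNIT_INTERVAL_COLS:
            lo, hi = 0.0, 1.0
        elif col in _NON_NEGATIVE_COLS:
            lo = 0.0
        elif col in _POSITIVE_COLS:
            lo, strict = 0.0, True
        if lo is None:
            continue
        vals = df[col].to_numpy(dtype=float)
        bad = (vals <= lo) if strict else (vals < lo)
        if hi is not None:
            bad |= vals > hi
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            detail = ""
            if "disease" in df.columns:
                detail = f" (disease={df['disease'].iloc[row]}"
                detail += f", sex={df['sex'].iloc[row]}, age_start={df['age_start'].iloc[row]})" \
                    if "sex" in df.columns else ")"
            elif "sex" in df.columns:
                detail = f" (sex={df['sex'].iloc[row]}, age_start={df['age_start'].iloc[row]})"
            bound = f"({lo}, {hi}]" if strict else (f"[{lo}, {hi}]" if hi is not None else f">= {lo}")
            raise BoundViolationError(
                f"value {vals[row]} outside bound {bound}{detail}",
                file=fname, row=row, column=col)


def _read_table(path: str, fname: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = SCHEMAS[fname]
    for col in schema:
        if col not in df.columns:
            raise MissingColumnError("required column missing", file=fname, column=col)
    df = df[schema]
    str_cols = {"sex", "disease", "affected_by", "person_id", "food_group", "from_category"}
    for col in schema:
        if col in str_cols:
            continue
        if col in ("age_start", "age_width"):
            df[col] = _coerce_numeric(df, col, fname).astype(int)
        else:
            df[col] = _coerce_numeric(df, col, fname).astype(float)
    if "sex" in df.columns:
        bad = ~df["sex"].isin(SEXES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise BoundViolationError(
                f"sex must be one of {SEXES}, got {df['sex'].iloc[row]!r}",
                file=fname, row=row, column="sex")
    _check_bounds(df, fname)
    return canonical_sort(df)


def _stratum_set(df: pd.DataFrame) -> set[tuple]:
    return set(map(tuple, df[STRATUM_COLS].itertuples(index=False)))


def _check_strata_match(reference: pd.DataFrame, df: pd.DataFrame, fname: str,
                        per: str | None = None) -> None:
    ref = _stratum_set(reference)
    if per is None:
        groups = [(None, df)]
    else:
        groups = list(df.groupby(per, sort=False))
    for key, sub in groups:
        got = _stratum_set(sub)
        if got != ref:
            missing = sorted(ref - got)[:3]
            extra = sorted(got - ref)[:3]
            what = f" for {per}={key}" if per else ""
            raise StratumMismatchError(
                f"strata{what} do not match population strata "
                f"(missing {missing}, unexpected {extra})",
                file=fname)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_inputs(directory: str | os.PathLike,
                schema_version: str = SCHEMA_VERSION) -> ModelInputs:
    """Load and validate a full input bundle from a directory of CSVs.

    Raises a named validation failure (missing column, non-numeric cell,
    bound violation, stratum mismatch) identifying file, row and column.
    """
    if schema_version != SCHEMA_VERSION:
        raise InputValidationError(
            f"unsupported schema version {schema_version!r}; this build reads {SCHEMA_VERSION!r}")
    directory = os.fspath(directory)
    tables: dict[str, pd.DataFrame] = {}
    for fname in CORE_FILES:
        path = os.path.join(directory, fname)
        if not os.path.exists(path):
            raise InputValidationError("required input file missing", file=fname)
        tables[fname] = _read_table(path, fname)
    for fname in PATHWAY_FILES:
        path = os.path.join(directory, fname)
        tables[fname] = _read_table(path, fname) if os.path.exists(path) else None

    pop = tables["population.csv"]
    for sex in SEXES:
        if not (pop["sex"] == sex).any():
            raise StratumMismatchError(
                f"population has no {sex} strata", file="population.csv")
    _check_band_layout(pop, "population.csv")
    _check_strata_match(pop, tables["mortality.csv"], "mortality.csv")
    _check_strata_match(pop, tables["disease_epi.csv"], "disease_epi.csv", per="disease")
    _check_strata_match(pop, tables["utilities.csv"], "utilities.csv")
    _check_strata_match(pop, tables["social_care.csv"], "social_care.csv")
    if tables["salt_sbp_model.csv"] is not None:
        _check_strata_match(pop, tables["salt_sbp_model.csv"], "salt_sbp_model.csv")
    if tables["bp_disease_rr.csv"] is not None:
        _check_strata_match(pop, tables["bp_disease_rr.csv"], "bp_disease_rr.csv", per="disease")

    registry = tables["disease_registry.csv"]
    missing_core = set(CORE_DISEASES) - set(registry["disease"])
    if missing_core:
        raise BoundViolationError(
            f"disease registry must contain at least {sorted(CORE_DISEASES)}; "
            f"missing {sorted(missing_core)}", file="disease_registry.csv")
    epi_diseases = set(tables["disease_epi.csv"]["disease"])
    unknown = epi_diseases - set(registry["disease"])
    if unknown:
        raise StratumMismatchError(
            f"disease_epi contains diseases absent from the registry: {sorted(unknown)}",
            file="disease_epi.csv")

    _warn_mortality_gradient(tables["mortality.csv"])

    return ModelInputs(
        population=pop,
        mortality=tables["mortality.csv"],
        disease_epi=tables["disease_epi.csv"],
        registry=registry,
        utilities=tables["utilities.csv"],
        social_care=tables["social_care.csv"],
        salt_sbp=tables["salt_sbp_model.csv"],
        bp_rr=tables["bp_disease_rr.csv"],
        pa_rr=tables["pa_rr.csv"],
        schema_version=schema_version,
    )


def _warn_mortality_gradient(mort: pd.DataFrame) -> None:
    # sanity check only: all-cause mortality should not fall across the
    # oldest three age bands
    for sex, sub in mort.groupby("sex"):
        tail = sub.sort_values("age_start")["all_cause_mortality"].to_numpy()[-3:]
        if len(tail) == 3 and (np.diff(tail) < 0).any():
            logger.warning(
                "all-cause mortality decreases across the oldest three %s age bands", sex)


def _check_band_layout(df: pd.DataFrame, fname: str,
                       group_cols: Iterable[str] = ("sex",)) -> None:
    for _, sub in df.groupby(list(group_cols), sort=False):
        sub = sub.sort_values("age_start")
        starts = sub["age_start"].to_numpy()
        widths = sub["age_width"].to_numpy()
        for i in range(1, len(starts)):
            expected = starts[i - 1] + widths[i - 1]
            if starts[i] < expected:
                raise BandContiguityError(
                    f"age bands overlap at age_start={starts[i]}", file=fname)
            if starts[i] > expected:
                raise BandContiguityError(
                    f"gap in age bands between {starts[i-1]} and {starts[i]}", file=fname)


def expand_age_bands(table: pd.DataFrame,
                     count_cols: Iterable[str] = ()) -> pd.DataFrame:
    """Expand a 5-year-band table to single years of age.

    Rate- and cost-per-person columns are copied piecewise-constant into
    each year of the band; columns named in ``count_cols`` (population
    counts) are split evenly across the band's years.  Band totals of count
    columns and band means of rate columns are preserved exactly.
    """
    if (table["age_width"] == 1).all():
        return table.reset_index(drop=True)
    group_cols = [c for c in ("disease",) if c in table.columns] + ["sex"]
    _check_band_layout(table, "<in-memory>", group_cols=group_cols)
    count_cols = set(count_cols)
    widths = table["age_width"].to_numpy(dtype=int)
    expanded = table.loc[table.index.repeat(widths)].reset_index(drop=True)
    offsets = np.concatenate([np.arange(w) for w in widths])
    expanded["age_start"] = expanded["age_start"].to_numpy() + offsets
    for col in count_cols:
        expanded[col] = expanded[col].to_numpy() / np.repeat(widths, widths)
    expanded["age_width"] = 1
    return canonical_sort(expanded)


def validate_consistency(inputs: ModelInputs) -> ConsistencyReport:
    """Check, per stratum, that summed disease deaths (prevalence x case
    fatality over diseases) do not exceed all-cause mortality."""
    epi = inputs.disease_epi
    if len(epi):
        rate = (epi["prevalence"] * epi["case_fatality"]).groupby(
            [epi[c] for c in STRATUM_COLS]).sum().rename("disease_death_rate").reset_index()
    else:
        rate = inputs.strata
        rate["disease_death_rate"] = 0.0
    frame = inputs.mortality.merge(rate, on=STRATUM_COLS, how="left")
    frame["disease_death_rate"] = frame["disease_death_rate"].fillna(0.0)
    frame["ok"] = frame["disease_death_rate"] <= frame["all_cause_mortality"] + 1e-12
    violations = [
        Stratum(sex=r.sex, age_start=int(r.age_start), age_width=int(r.age_width))
        for r in frame[~frame["ok"]].itertuples()
    ]
    return ConsistencyReport(frame=canonical_sort(frame), violations=violations)


def write_inputs(inputs: ModelInputs, directory: str | os.PathLike) -> list[str]:
    """Write a bundle back to CSV in canonical column and row order.

    Floats are written with Python's shortest round-trip representation, so
    ``write_inputs(load_inputs(p))`` reproduces byte-identical files.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    mapping = {
        "population.csv": inputs.population,
        "mortality.csv": inputs.mortality,
        "disease_epi.csv": inputs.disease_epi,
        "disease_registry.csv": inputs.registry,
        "utilities.csv": inputs.utilities,
        "social_care.csv": inputs.social_care,
        "salt_sbp_model.csv": inputs.salt_sbp,
        "bp_disease_rr.csv": inputs.bp_rr,
        "pa_rr.csv": inputs.pa_rr,
    }
    written = []
    for fname, df in mapping.items():
        if df is None:
            continue
        path = os.path.join(directory, fname)
        out = canonical_sort(df[SCHEMAS[fname]])
        out.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written


def hazard_to_annual_risk(hazard: float | np.ndarray) -> float | np.ndarray:
    """Convert an instantaneous hazard to an annual risk, 1 - exp(-h).

    Internally all rates are annual risks (probabilities); any hazard-form
    input must pass through this at load time.
    """
    return 1.0 - np.exp(-np.asarray(hazard, dtype=float))
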