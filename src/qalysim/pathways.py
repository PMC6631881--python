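"""Risk-factor pathways: converting exposure changes into incidence rate
ratios.

Two mechanisms are supported, matching the two intervention families:

* a continuous exposure (dietary salt, g/day) acting through systolic blood
  pressure — a per-stratum mean shift is translated into a SBP change and
  then into a log-linear incidence multiplier ``RR ** delta_SBP`` for the
  blood-pressure-mediated diseases (IHD and stroke);
* a categorical physical-activity distribution over the four categories
  sedentary / under-active / active / recommended, translated into a
  potential impact fraction (PIF) per disease, with incidence multiplier
  ``1 - PIF``.

The same log-linear machinery serves any mediated continuous exposure (BMI,
serum cholesterol); only blood-pressure parameter tables ship here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epidata import CATEGORIES, STRATUM_COLS, BoundViolationError

__all__ = [
    "ContinuousExposureShift",
    "CategoryDistribution",
    "validate_distribution",
    "salt_to_sbp_shift",
    "rate_ratio_from_bp_shift",
    "pif_categorical",
    "apply_category_transitions",
]

#: Diseases mediated by blood pressure.
BP_DISEASES = ("ihd", "stroke")
#: Diseases affected by physical activity.
PA_DISEASES = ("ihd", "stroke", "type2_diabetes", "breast_cancer", "colorectal_cancer")

_SUM_TOL = 1e-12


@dataclass
class ContinuousExposureShift:
    """Per-stratum change in a continuous exposure (negative = reduction).

    ``table`` columns: the stratum columns plus ``delta_mean`` (exposure
    units, e.g. g salt/day) and ``se_delta`` (standard error of the
    difference, same units, >= 0).
    """

    table: pd.DataFrame

    def __post_init__(self):
        need = STRATUM_COLS + ["delta_mean", "se_delta"]
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise BoundViolationError(f"exposure shift missing columns {missing}")
        if (self.table["se_delta"] < 0).any():
            raise BoundViolationError("se_delta must be >= 0")


def validate_distribution(p) -> np.ndarray:
    """Validate a four-category activity distribution (sums to 1 within
    1e-12, each share in [0, 1]) and return it as an array."""
    arr = np.asarray(p, dtype=float)
    if arr.shape[-1] != len(CATEGORIES):
        raise BoundViolationError(
            f"distribution must have {len(CATEGORIES)} categories, got {arr.shape[-1]}")
    if (arr < -_SUM_TOL).any() or (arr > 1 + _SUM_TOL).any():
        raise BoundViolationError("category proportions must lie in [0, 1]")
    sums = arr.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-9:
        raise BoundViolationError(f"category proportions must sum to 1, got {sums}")
    return arr


#: Convenience alias: a CategoryDistribution is a length-4 array over
#: ``epidata.CATEGORIES`` validated by :func:`validate_distribution`.
CategoryDistribution = np.ndarray


def salt_to_sbp_shift(shift: ContinuousExposureShift,
                      model: pd.DataFrame) -> pd.DataFrame:
    """Translate a per-stratum salt change (g/day) into a systolic blood
    pressure change (mmHg): ``delta_SBP = delta_mean * mmhg_per_gram``.

    ``model`` is the salt->SBP dose-response table (stratum columns +
    ``mmhg_per_gram`` >= 0).  Sign is preserved: a salt reduction (negative
    delta) yields a blood-pressure fall (negative mmHg).
    """
    if (model["mmhg_per_gram"] < 0).any():
        raise BoundViolationError("mmhg_per_gram must be >= 0")
    merged = shift.table.merge(model, on=STRATUM_COLS, validate="one_to_one")
    merged["delta_sbp"] = merged["delta_mean"] * merged["mmhg_per_gram"]
    return merged[STRATUM_COLS + ["delta_sbp"]]


def rate_ratio_from_bp_shift(delta_sbp, rr_per_mmhg):
    """Log-linear incidence multiplier for a blood-pressure shift:
    ``multiplier = rr_per_mmhg ** delta_sbp``.

    Equals 1 at no shift; below 1 for a BP fall whenever the relative risk
    per +1 mmHg exceeds 1.  Accepts scalars or aligned arrays.
    """
    rr = np.asarray(rr_per_mmhg, dtype=float)
    if (rr <= 0).any():
        raise BoundViolationError("rr_per_mmhg must be > 0")
    return rr ** np.asarray(delta_sbp, dtype=float)


def pif_categorical(baseline, scenario, rr) -> float:
    """Potential impact fraction of moving the population between two
    category distributions:

        PIF = (sum_i p_i RR_i - sum_i p'_i RR_i) / sum_i p_i RR_i

    Positive when the scenario moves mass toward lower-risk categories (the
    incidence multiplier is ``1 - PIF``); negative (harm) when mass moves
    toward higher-risk categories.  Never exceeds 1 for positive RRs.
    """
    rr = np.asarray(rr, dtype=float)
    if (rr <= 0).any():
        raise BoundViolationError("relative risks must be > 0")
    b = np.asarray(baseline, dtype=float)
    s = np.asarray(scenario, dtype=float)
    before = float(b @ rr)
    after = float(s @ rr)
    if before <= 0:
        raise ZeroDivisionError("baseline risk-weighted sum is zero")
    return (before - after) / before


def apply_category_transitions(baseline, participation: float,
                               transitions: np.ndarray,
                               include_sedentary: bool = False) -> np.ndarray:
    """Move a participating fraction of the population between activity
    categories.

    ``participation`` applies only to the non-sedentary mass (programme
    participants are, by definition, not sedentary) unless
    ``include_sedentary`` is set.  ``transitions`` is a row-stochastic 4x4
    matrix over ``epidata.CATEGORIES`` describing where participants in
    each category end up; non-participants stay put.  Total probability
    mass is conserved.
    """
    base = validate_distribution(baseline)
    if not 0.0 <= participation <= 1.0:
        raise BoundViolationError("participation must lie in [0, 1]")
    T = np.asarray(transitions, dtype=float)
    if T.shape != (len(CATEGORIES), len(CATEGORIES)):
        raise BoundViolationError(f"transition matrix must be {len(CATEGORIES)}x{len(CATEGORIES)}")
    if (T < 0).any() or np.abs(T.sum(axis=1) - 1.0).max() > 1e-9:
        raise BoundViolationError("transition rows must be non-negative and sum to 1")

    mask = np.ones(len(CATEGORIES))
    if not include_sedentary:
        mask[CATEGORIES.index("sedentary")] = 0.0
    participants = base * participation * mask
    moved = participants @ T
    result = base - participants + moved
    return validate_distribution(result)
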