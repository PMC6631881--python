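"""Probabilistic sensitivity analysis.

Every uncertain parameter is declared as a :class:`ParameterDistribution`;
a Monte Carlo run draws all of them, reruns the full pipeline per
iteration, and summarises medians, means, 95% uncertainty intervals and
the probability of falling below configured cost-per-QALY thresholds.

Random-number discipline: one root seed spawns an independent,
counter-based substream per iteration (``default_rng([seed, i])``), so
results are bit-identical under a fixed seed regardless of execution
order, and increasing the iteration count leaves earlier iterations
unchanged.  Ratio quantities (ICER, ROI) are computed per iteration and
then summarised — medians of ratios, not ratios of medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import DiscountSpec, ScenarioResult, evaluate_scenario
from .lifetable import run_cohort

__all__ = [
    "ParameterDistribution",
    "sample_parameter",
    "IterationRecord",
    "MCSummary",
    "MCResult",
    "run_monte_carlo",
    "summarize",
    "DEFAULT_THRESHOLDS",
]

#: Cost-per-QALY decision thresholds (GBP/QALY) reported by default.
DEFAULT_THRESHOLDS = (20_000.0, 30_000.0)

_KINDS = ("fixed", "normal", "lognormal", "triangular", "beta")


@dataclass(eq=False)
class ParameterDistribution:
    """An uncertain parameter: a distribution kind, its parameters, and the
    dotted path of the model quantity it perturbs.

    Kinds and parameters: ``fixed(value)``, ``normal(mean, sd)`` (mean/sd
    may be aligned arrays for per-stratum effects), ``lognormal(log_mean,
    log_sd)``, ``triangular(low, mode, high)``, ``beta(alpha, beta)``.
    """

    kind: str
    target: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        p = self.params
        if self.kind == "fixed" and "value" not in p:
            raise ValueError("fixed distribution requires a value")
        if self.kind == "normal":
            if np.any(np.asarray(p["sd"]) < 0):
                raise ValueError("normal sd must be >= 0")
        if self.kind == "lognormal":
            if np.any(np.asarray(p["log_sd"]) < 0):
                raise ValueError("lognormal log_sd must be >= 0")
        if self.kind == "triangular":
            low, mode, high = p["low"], p["mode"], p["high"]
            if not low <= mode <= high:
                raise ValueError("triangular requires low <= mode <= high")
        if self.kind == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValueError("beta requires alpha, beta > 0")


def sample_parameter(dist: ParameterDistribution, rng: np.random.Generator):
    """One draw from a parameter distribution (within its support)."""
    p = dist.params
    if dist.kind == "fixed":
        return p["value"]
    if dist.kind == "normal":
        mean = np.asarray(p["mean"], dtype=float)
        sd = np.asarray(p["sd"], dtype=float)
        draw = rng.normal(mean, sd)
        return float(draw) if np.ndim(draw) == 0 else draw
    if dist.kind == "lognormal":
        return float(rng.lognormal(p["log_mean"], p["log_sd"]))
    if dist.kind == "triangular":
        if p["low"] == p["high"]:
            return float(p["low"])  # degenerate support
        return float(rng.triangular(p["low"], p["mode"], p["high"]))
    if dist.kind == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    raise AssertionError(dist.kind)


# ---------------------------------------------------------------------------
# Monte Carlo driver
# ---------------------------------------------------------------------------

@dataclass
class IterationRecord:
    """Outcome quantities of one Monte Carlo iteration."""

    index: int
    delta_qalys: float
    delta_cost: float
    nhs_saving: float
    social_saving: float
    intervention_cost: float
    classification: str
    icer: float = math.nan
    roi: float = math.nan


@dataclass
class MCResult:
    iterations: list[IterationRecord]
    seed: int
    summary: "MCSummary"

    @property
    def ce_plane(self) -> pd.DataFrame:
        """Cost-effectiveness plane: one (delta QALY, delta cost) point per
        iteration."""
        return pd.DataFrame({
            "iteration": [r.index for r in self.iterations],
            "delta_qaly": [r.delta_qalys for r in self.iterations],
            "delta_cost": [r.delta_cost for r in self.iterations],
        })


@dataclass
class QuantitySummary:
    median: float
    mean: float
    p2_5: float
    p97_5: float
    n_defined: int

    def as_dict(self) -> dict:
        return {"median": self.median, "mean": self.mean,
                "p2.5": self.p2_5, "p97.5": self.p97_5,
                "n_defined": self.n_defined}


@dataclass
class MCSummary:
    """Medians, means, 95% uncertainty intervals and threshold
    probabilities across Monte Carlo iterations."""

    quantities: dict[str, QuantitySummary]
    threshold_probabilities: dict[float, float]
    n_iterations: int
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "quantities": {k: v.as_dict() for k, v in self.quantities.items()},
            "threshold_probabilities": {
                str(k): v for k, v in self.threshold_probabilities.items()},
        }


def _record_from_result(i: int, result: ScenarioResult) -> IterationRecord:
    s, ce = result.summary, result.ce
    return IterationRecord(
        index=i,
        delta_qalys=s.delta_qalys,
        delta_cost=s.delta_cost,
        nhs_saving=s.nhs_saving,
        social_saving=s.social_saving,
        intervention_cost=s.c_i,
        classification=ce.classification,
        icer=math.nan if ce.icer is None else ce.icer,
        roi=math.nan if ce.roi is None else ce.roi,
    )


def run_monte_carlo(inputs, scenario, n_iterations: int = 2000,
                    seed: int = 0, horizon: int | None = 10,
                    discount: DiscountSpec = DiscountSpec(),
                    include_industry_costs: bool = True,
                    perspective: str = "health_and_social",
                    thresholds=DEFAULT_THRESHOLDS) -> MCResult:
    """Rerun the full pipeline ``n_iterations`` times with all declared
    parameter distributions sampled, and summarise.

    Iteration *i* depends only on ``(seed, i)``; rerunning with the same
    seed is bit-identical.  Any iteration's validation failure aborts the
    run with the iteration index attached.
    """
    baseline = run_cohort(inputs, None, horizon)
    records = []
    for i in range(n_iterations):
        rng = np.random.default_rng([seed, i])
        try:
            sampled = scenario.sampled(rng)
            result = evaluate_scenario(
                inputs, sampled, horizon=horizon, discount=discount,
                include_industry_costs=include_industry_costs,
                perspective=perspective, baseline=baseline)
        except Exception as exc:
            raise RuntimeError(f"Monte Carlo iteration {i} failed: {exc}") from exc
        records.append(_record_from_result(i, result))
    summary = summarize(records, thresholds=thresholds, seed=seed)
    return MCResult(iterations=records, seed=seed, summary=summary)


def summarize(iterations: list[IterationRecord],
              thresholds=DEFAULT_THRESHOLDS,
              seed: int | None = None) -> MCSummary:
    """Median, mean and 95% uncertainty interval per output quantity
    (linear-interpolation percentiles), plus the probability that the
    intervention falls below each cost-per-QALY threshold (dominant
    iterations count as below any positive threshold)."""
    if not iterations:
        raise ValueError("summarize requires at least one iteration")
    arrays = {
        "delta_qalys": np.array([r.delta_qalys for r in iterations]),
        "delta_cost": np.array([r.delta_cost for r in iterations]),
        "nhs_saving": np.array([r.nhs_saving for r in iterations]),
        "social_saving": np.array([r.social_saving for r in iterations]),
        "intervention_cost": np.array([r.intervention_cost for r in iterations]),
        "icer": np.array([r.icer for r in iterations]),
        "roi": np.array([r.roi for r in iterations]),
    }
    quantities = {}
    for name, arr in arrays.items():
        defined = arr[~np.isnan(arr)]
        if len(defined) == 0:
            continue
        quantities[name] = QuantitySummary(
            median=float(np.median(defined)),
            mean=float(np.mean(defined)),
            p2_5=float(np.percentile(defined, 2.5)),
            p97_5=float(np.percentile(defined, 97.5)),
            n_defined=int(len(defined)),
        )
    n = len(iterations)
    probs = {}
    for thr in thresholds:
        below = sum(
            1 for r in iterations
            if r.classification == "dominant"
            or (r.classification == "icer" and r.delta_qalys > 0 and r.icer < thr)
        )
        probs[float(thr)] = below / n
    return MCSummary(quantities=quantities, threshold_probabilities=probs,
                     n_iterations=n, seed=seed)
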