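"""Deterministic one-way (tornado) sensitivity analysis and scenario analyses.

The tornado varies one input at a time between its published low/high bounds,
reruns the deterministic comparison, and ranks inputs by the induced swing in
the net-benefit difference.  Three bound rows need derived recomputation:

* ``trim_probability`` (bounds on the overall fraction of the herd trimmed
  per partial session) scales both conditional selection probabilities
  proportionally by bound / 0.18, preserving the targeting ratio;
* ``block_unit_cost`` and ``block_probability`` recompute the expected
  block cost per ulcer trim as price x application probability;
* ``labor_cost`` treats the hourly wage as the varied quantity, so the
  partial (45 min) and whole-herd (10 min) session costs move together.

Scenarios:

1. random selection — both partial-herd selection probabilities follow the
   overall 18% trim probability (one shared draw per PSA iteration);
2. targeting sweep — selection of ulcer cows at 0.18 / 0.54 / 1.00 under a
   fixed 324-trim budget, enforced through the healthy-cow probability;
3. herd-size sweep — deterministic difference across 50..500 cows;
4. no quota — production loss priced as direct milk loss instead of the
   fractional additional cow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import run_cohort
from .economics import compare_strategies
from .parameters import ModelConfig, SensitivityBound
from .psa import PsaResult, run_psa

__all__ = [
    "TornadoEntry",
    "ScenarioResult",
    "reference_bounds",
    "apply_parameter",
    "one_way_sensitivity",
    "scenario_random_selection",
    "solve_nonulcer_trim_probability",
    "scenario_targeting_sweep",
    "scenario_herd_size_sweep",
    "scenario_no_quota",
]

#: Reference overall fraction of the herd trimmed per partial session; the
#: tornado's trim-probability bounds are expressed on this scale.
_REFERENCE_OVERALL_TRIM = 0.18

#: Session durations behind the labor costs (hours).
_PARTIAL_SORT_HOURS = 45 / 60
_WHOLE_SORT_HOURS = 10 / 60


@dataclass(frozen=True)
class TornadoEntry:
    """One input varied to its bounds and the resulting swing."""

    param_name: str
    low_value: float
    high_value: float
    difference_at_low: float
    difference_at_high: float

    @property
    def range_width(self) -> float:
        return abs(self.difference_at_high - self.difference_at_low)


@dataclass(frozen=True)
class ScenarioResult:
    """Output table of one scenario plus headline statistics."""

    scenario_id: str
    description: str
    table: pd.DataFrame
    stats: dict[str, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.table.empty:
            raise ValueError(f"scenario {self.scenario_id}: empty output table")


def reference_bounds() -> list[SensitivityBound]:
    """The published low/high limits for the one-way sensitivity analysis."""
    return [
        SensitivityBound("herd_size", 50, 500),
        SensitivityBound("prevalence", 0.014, 0.28),
        SensitivityBound("trim_probability", 0.10, 0.30),
        SensitivityBound("cure_probability_trim", 0.68, 0.97),
        SensitivityBound("cure_probability_no_trim", 0.10, 0.40),
        SensitivityBound("incidence_risk", 0.009, 0.315),
        SensitivityBound("trim_cost", 13.48, 16.56),
        SensitivityBound("block_unit_cost", 26.95, 30.80),
        SensitivityBound("block_probability", 0.50, 0.95),
        SensitivityBound("labor_cost", 13.29, 13.39),
        SensitivityBound("additional_cow_cost", 75.37, 135.40),
        SensitivityBound("ai_cost_shift", -38.50, 38.50),
        SensitivityBound("milk_sales", 5802.82, 6698.71),
        SensitivityBound("cattle_sales", 248.49, 333.54),
    ]


def apply_parameter(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """Return a config with one (possibly derived) sensitivity input set."""
    if name == "herd_size":
        return replace(config, herd_size=int(round(value)))
    if name in config.probabilities and name != "block_probability":
        return config.with_probability(name, value)
    if name == "trim_probability":
        factor = value / _REFERENCE_OVERALL_TRIM
        cfg = config.with_probability(
            "trim_probability_ulcer",
            min(1.0, config.prob("trim_probability_ulcer") * factor),
        )
        return cfg.with_probability(
            "trim_probability_healthy",
            min(1.0, config.prob("trim_probability_healthy") * factor),
        )
    if name == "block_unit_cost":
        return replace(config, block_price=value).with_cost(
            "block_cost", value * config.prob("block_probability")
        )
    if name == "block_probability":
        return config.with_probability("block_probability", value).with_cost(
            "block_cost", config.block_price * value
        )
    if name == "labor_cost":
        wage = value / _PARTIAL_SORT_HOURS
        return config.with_cost("labor_partial", value).with_cost(
            "labor_whole", wage * _WHOLE_SORT_HOURS
        )
    if name == "ai_cost_shift":
        return config.with_cost(
            "ai_cost_no_ulcer", config.cost("ai_cost_no_ulcer") + value
        ).with_cost("ai_cost_ulcer", config.cost("ai_cost_ulcer") + value)
    if name in config.costs:
        return config.with_cost(name, value)
    raise ValueError(f"unknown sensitivity parameter: {name}")


def one_way_sensitivity(
    config: ModelConfig,
    bounds: Sequence[SensitivityBound] | None = None,
    production_cost_mode: str = "additional_cow",
) -> list[TornadoEntry]:
    """Tornado entries sorted by descending swing in the net-benefit difference."""
    bounds = reference_bounds() if bounds is None else bounds
    entries = []
    for b in bounds:
        diff_low = compare_strategies(
            apply_parameter(config, b.param_name, b.low), production_cost_mode
        ).difference
        diff_high = compare_strategies(
            apply_parameter(config, b.param_name, b.high), production_cost_mode
        ).difference
        entries.append(
            TornadoEntry(b.param_name, b.low, b.high, diff_low, diff_high)
        )
    return sorted(entries, key=lambda e: e.range_width, reverse=True)


def tornado_to_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "param_name": [e.param_name for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "difference_at_low": [e.difference_at_low for e in entries],
            "difference_at_high": [e.difference_at_high for e in entries],
            "range_width": [e.range_width for e in entries],
        }
    )


# -- Scenario 1: random (non-targeted) selection -------------------------------


def random_selection_config(config: ModelConfig) -> ModelConfig:
    """Point both partial-herd selection probabilities at the overall 18%.

    Both policy slots reference the same parameter, so the probabilistic
    analysis draws a single Beta(43.74, 199.26) value per iteration and uses
    it for cows with and without an ulcer alike — selection carries no
    information about ulcer status.
    """
    return replace(
        config,
        policy_ulcer_param="trim_probability_overall",
        policy_healthy_param="trim_probability_overall",
    )


def scenario_random_selection(
    config: ModelConfig, n_iter: int | None = None, seed: int | None = None
) -> ScenarioResult:
    """Scenario 1: PSA with random 18% selection regardless of ulcer status.

    The headline is reported from the whole-herd perspective (whole minus
    partial), matching the direction in which this scenario is usually read.
    """
    psa = run_psa(random_selection_config(config), n_iter, seed)
    whole_minus_partial = -psa.differences
    table = pd.DataFrame({"iteration": np.arange(psa.n_iterations), "whole_minus_partial": whole_minus_partial})
    return ScenarioResult(
        scenario_id="1",
        description="random 18% selection in the partial herd trim",
        table=table,
        stats={
            "mean_whole_minus_partial": float(whole_minus_partial.mean()),
            "ci_low": float(np.percentile(whole_minus_partial, 2.5)),
            "ci_high": float(np.percentile(whole_minus_partial, 97.5)),
            "fraction_whole_preferred": float(np.mean(whole_minus_partial > 0)),
            "fraction_partial_preferred": psa.fraction_partial_preferred,
        },
        seed=psa.seed,
    )


# -- Scenario 2: targeting sweep at a fixed trim budget ------------------------


def _expected_trims_for(config: ModelConfig, p_ulcer: float, p_healthy: float) -> float:
    cfg = config.with_probability(config.policy_ulcer_param, p_ulcer)
    cfg = cfg.with_probability(cfg.policy_healthy_param, p_healthy)
    return run_cohort(cfg, "partial").expected_trims_total


def solve_nonulcer_trim_probability(
    p_trim_ulcer: float, trim_budget: float, config: ModelConfig
) -> float:
    """Healthy-cow selection probability that spends exactly the trim budget.

    Expected trims are monotone increasing in the healthy-cow probability but
    feed back on the prevalence trajectory (trimming cures, lowering future
    ulcer trims), so the root is found numerically; the budget is matched to
    within 0.01 cow-trimmings.
    """
    if not 0.0 <= p_trim_ulcer <= 1.0:
        raise ValueError(f"p_trim_ulcer {p_trim_ulcer} outside [0, 1]")
    lo = _expected_trims_for(config, p_trim_ulcer, 0.0)
    hi = _expected_trims_for(config, p_trim_ulcer, 1.0)
    if not lo <= trim_budget <= hi:
        raise ValueError(
            f"trim budget {trim_budget} infeasible: achievable range [{lo:.2f}, {hi:.2f}]"
        )
    p = optimize.brentq(
        lambda ph: _expected_trims_for(config, p_trim_ulcer, ph) - trim_budget,
        0.0,
        1.0,
        xtol=1e-12,
    )
    if abs(_expected_trims_for(config, p_trim_ulcer, p) - trim_budget) > 0.01:
        raise RuntimeError("budget solve did not converge to within 0.01 trims")
    return float(p)


def scenario_targeting_sweep(
    config: ModelConfig,
    ulcer_trim_probs: Sequence[float] = (0.18, 0.54, 1.00),
    trim_budget: float = 324.0,
    production_cost_mode: str = "additional_cow",
    n_iter: int | None = None,
    seed: int | None = None,
) -> ScenarioResult:
    """Scenario 2: difference vs targeting level at a fixed trim budget.

    For each targeting level the healthy-cow selection probability is solved
    deterministically so the partial arm spends exactly ``trim_budget``
    cow-trimmings, then the deterministic difference is computed; if
    ``n_iter`` is given, the selection pair is additionally held fixed
    through a PSA and the probabilistic mean difference is reported
    alongside.  Both columns increase with the targeting level.
    """
    rows = []
    for pu in ulcer_trim_probs:
        ph = solve_nonulcer_trim_probability(pu, trim_budget, config)
        cfg = config.with_probability(config.policy_ulcer_param, pu)
        cfg = cfg.with_probability(cfg.policy_healthy_param, ph)
        trims = run_cohort(cfg, "partial").expected_trims_total
        diff = compare_strategies(cfg, production_cost_mode).difference
        row = [pu, ph, trims, diff]
        if n_iter is not None:
            # freeze the solved selection pair: strip their Beta specs so the
            # budget holds in every draw, then sample everything else
            probs = dict(cfg.probabilities)
            for pname in (cfg.policy_ulcer_param, cfg.policy_healthy_param):
                probs[pname] = replace(probs[pname], alpha=None, beta_=None)
            psa = run_psa(replace(cfg, probabilities=probs), n_iter, seed, production_cost_mode)
            row.append(psa.mean_difference)
        rows.append(tuple(row))
    columns = ["p_trim_ulcer", "p_trim_healthy", "expected_trims", "difference"]
    if n_iter is not None:
        columns.append("mean_difference_psa")
    table = pd.DataFrame(rows, columns=columns)
    return ScenarioResult(
        scenario_id="2",
        description=f"targeting sweep at a fixed budget of {trim_budget} trims",
        table=table,
        stats={"trim_budget": float(trim_budget)},
        seed=seed,
    )


# -- Scenario 3: herd-size sweep ----------------------------------------------


def scenario_herd_size_sweep(
    config: ModelConfig,
    sizes: Sequence[int] = (50, 100, 150, 200, 250, 300, 350, 400, 450, 500),
    production_cost_mode: str = "additional_cow",
) -> ScenarioResult:
    """Scenario 3: deterministic difference across herd sizes, with linear fit.

    Labor is the only per-session (herd-size-independent) component, so the
    difference is exactly affine in herd size; the fit summarises the line.
    """
    diffs = [
        compare_strategies(replace(config, herd_size=n), production_cost_mode).difference
        for n in sizes
    ]
    fit = stats.linregress(sizes, diffs)
    table = pd.DataFrame({"herd_size": list(sizes), "difference": diffs})
    return ScenarioResult(
        scenario_id="3",
        description="net-benefit difference vs herd size",
        table=table,
        stats={
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
        },
    )


# -- Scenario 4: no quota system ----------------------------------------------


def scenario_no_quota(
    config: ModelConfig, n_iter: int | None = None, seed: int | None = None
) -> ScenarioResult:
    """Scenario 4: PSA with production loss priced as direct milk loss."""
    psa = run_psa(config, n_iter, seed, production_cost_mode="milk_loss")
    table = pd.DataFrame(
        {"iteration": np.arange(psa.n_iterations), "difference": psa.differences}
    )
    return ScenarioResult(
        scenario_id="4",
        description="milk-loss production cost (no supply-management quota)",
        table=table,
        stats={
            "mean_difference": psa.mean_difference,
            "ci_low": psa.ci_low,
            "ci_high": psa.ci_high,
            "fraction_partial_preferred": psa.fraction_partial_preferred,
        },
        seed=psa.seed,
    )
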