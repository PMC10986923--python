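"""Probabilistic sensitivity analysis (PSA).

Every probability with a Beta specification is redrawn per iteration
(events = alpha, non-events = beta); every price is redrawn from
Normal(cad_mean, cad_sd) in CAD and converted to USD.  The per-cycle ulcer
onset probability is recomputed per draw from the drawn annual incidence
risk through the risk -> rate -> cycle-probability chain, so the PSA
mean responds nonlinearly to the incidence distribution — this is what
separates the probabilistic mean of the net-benefit difference from the
deterministic value.

Each iteration gets its own RNG stream spawned from the master seed
(``numpy.random.SeedSequence(seed).spawn``), so results do not depend on
execution order and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import run_cohort
from .economics import (
    COMPONENTS,
    CostBreakdown,
    accrue_costs,
    compare_strategies,
    discounted_benefits,
)
from .parameters import ModelConfig, cycle_probability_from_rate, rate_from_risk

__all__ = ["PsaDraw", "PsaResult", "sample_parameters", "run_psa", "summarize_psa"]


@dataclass(frozen=True)
class PsaDraw:
    """One joint draw of all uncertain inputs, resolved into a ModelConfig."""

    probabilities: dict[str, float]
    costs: dict[str, float]
    incidence_rate: float
    onset_probability: float
    config: ModelConfig


@dataclass(frozen=True)
class PsaResult:
    """Per-iteration differences and component breakdowns plus summaries."""

    n_iterations: int
    differences: np.ndarray  # partial minus whole, discounted, USD
    benefits: np.ndarray
    cost_partial: tuple[CostBreakdown, ...]
    cost_whole: tuple[CostBreakdown, ...]
    mean_difference: float
    ci_low: float  # empirical 2.5th percentile
    ci_high: float  # empirical 97.5th percentile
    fraction_partial_preferred: float
    seed: int
    production_cost_mode: str


def sample_parameters(config: ModelConfig, rng: np.random.Generator) -> PsaDraw:
    """Draw one parameter set; inputs without a distribution stay fixed.

    Negative Normal cost draws are resampled (with the printed CAD sd of 0.1
    this is effectively never triggered).
    """
    probs: dict[str, float] = {}
    for name, p in config.probabilities.items():
        probs[name] = float(rng.beta(p.alpha, p.beta_)) if p.has_distribution else p.value

    costs: dict[str, float] = {}
    for name, c in config.costs.items():
        if c.cad_sd > 0:
            cad = float(rng.normal(c.cad_mean, c.cad_sd))
            while cad < 0:
                cad = float(rng.normal(c.cad_mean, c.cad_sd))
            costs[name] = cad * config.fx_rate
        else:
            costs[name] = c.usd_value

    rate = rate_from_risk(probs["incidence_risk"])
    onset = cycle_probability_from_rate(rate, config.cycle_months / 12.0)

    resolved = config
    for name, v in probs.items():
        resolved = resolved.with_probability(name, v)
    new_costs = {
        name: replace(c, usd_value=costs[name], cad_mean=costs[name] / config.fx_rate)
        for name, c in config.costs.items()
    }
    resolved = replace(resolved, costs=new_costs)
    return PsaDraw(
        probabilities=probs,
        costs=costs,
        incidence_rate=rate,
        onset_probability=onset,
        config=resolved,
    )


def run_psa(
    config: ModelConfig,
    n_iter: int | None = None,
    seed: int | None = None,
    production_cost_mode: str = "additional_cow",
) -> PsaResult:
    """Run the full probabilistic comparison over ``n_iter`` iterations."""
    n_iter = config.psa_iterations if n_iter is None else n_iter
    seed = config.seed if seed is None else seed
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")

    children = np.random.SeedSequence(seed).spawn(n_iter)
    differences = np.empty(n_iter)
    benefits = np.empty(n_iter)
    cost_partial: list[CostBreakdown] = []
    cost_whole: list[CostBreakdown] = []
    for i in range(n_iter):
        draw = sample_parameters(config, np.random.default_rng(children[i]))
        result = compare_strategies(draw.config, production_cost_mode)
        differences[i] = result.difference
        benefits[i] = result.benefits_discounted
        cost_partial.append(result.cost_partial)
        cost_whole.append(result.cost_whole)

    mean = float(differences.mean())
    lo, hi = np.percentile(differences, [2.5, 97.5])
    return PsaResult(
        n_iterations=n_iter,
        differences=differences,
        benefits=benefits,
        cost_partial=tuple(cost_partial),
        cost_whole=tuple(cost_whole),
        mean_difference=mean,
        ci_low=float(lo),
        ci_high=float(hi),
        fraction_partial_preferred=float(np.mean(differences > 0)),
        seed=seed,
        production_cost_mode=production_cost_mode,
    )


_ROW_LABELS = {
    "trim_cost": "Cost of trim",
    "block_cost": "Cost of block",
    "reproduction_cost": "Cost of reproduction",
    "labor_cost": "Cost of labor",
    "su_production_cost": "Cost of production loss",
}


def summarize_psa(result: PsaResult) -> pd.DataFrame:
    """Summary table: per component and arm, mean and 95% percentile interval.

    Components are undiscounted; the total row is discounted, mirroring the
    reporting convention of the published cost table.  The difference row
    repeats the same statistics in both arm blocks.
    """
    if result.n_iterations < 1:
        raise ValueError("empty PSA result")

    def stats(values: np.ndarray) -> tuple[float, float, float]:
        return (
            float(values.mean()),
            float(np.percentile(values, 2.5)),
            float(np.percentile(values, 97.5)),
        )

    rows = []
    for comp in COMPONENTS:
        label = _ROW_LABELS[comp]
        if comp == "su_production_cost" and result.production_cost_mode == "additional_cow":
            label = "Cost of an additional cow"
        elif comp == "su_production_cost":
            label = "Cost of milk loss"
        part = np.array([b.component(comp) for b in result.cost_partial])
        whole = np.array([b.component(comp) for b in result.cost_whole])
        rows.append((label, *stats(part), *stats(whole)))

    part_tot = np.array([b.total_discounted for b in result.cost_partial])
    whole_tot = np.array([b.total_discounted for b in result.cost_whole])
    rows.append(("Total cost", *stats(part_tot), *stats(whole_tot)))
    rows.append(("Benefits", *stats(result.benefits), *stats(result.benefits)))
    diff_stats = stats(result.differences)
    rows.append(("Difference in net benefits", *diff_stats, *diff_stats))

    return pd.DataFrame(
        rows,
        columns=[
            "row",
            "partial_mean",
            "partial_ci_low",
            "partial_ci_high",
            "whole_mean",
            "whole_ci_low",
            "whole_ci_high",
        ],
    ).set_index("row")


def draws_to_frame(result: PsaResult) -> pd.DataFrame:
    """Per-iteration export: discounted totals per arm and the difference."""
    return pd.DataFrame(
        {
            "iteration": np.arange(result.n_iterations),
            "total_discounted_partial": [b.total_discounted for b in result.cost_partial],
            "total_discounted_whole": [b.total_discounted for b in result.cost_whole],
            "benefits_discounted": result.benefits,
            "difference": result.differences,
        }
    )
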