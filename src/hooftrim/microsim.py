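"""Per-cow stochastic microsimulation: the brute-force oracle for the cohort model.

Each cow is simulated independently with Bernoulli events in the same pinned
order as the cohort engine (select -> cure -> onset) and the same cost
accrual rules, so the cohort model's expected tallies are exactly the
expectations of the microsimulation.  Averaging many replicates and checking
the cohort expectations against the replicate means (within a few Monte
Carlo standard errors) is the structural correctness test of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import build_policy, run_cohort
from .economics import (
    COMPONENTS,
    CostBreakdown,
    PRODUCTION_COST_MODES,
    _yearly_sums,
    accrue_costs,
    discount_yearly,
)
from .parameters import ModelConfig

__all__ = ["MicrosimResult", "simulate_herd", "replicate_mean", "validate_against_cohort"]

#: Quantities tallied per replicate, in reporting order.
TALLIES = (
    "trims",
    "ulcer_trims",
    "ulcer_cow_cycles",
    "trim_cost",
    "block_cost",
    "reproduction_cost",
    "labor_cost",
    "su_production_cost",
    "total_discounted",
)


@dataclass(frozen=True)
class MicrosimResult:
    """Realized tallies for one arm: a single replicate or replicate means."""

    strategy: str
    tallies: dict[str, float]
    standard_errors: dict[str, float] | None
    n_replicates: int
    seed: int


def _simulate_arm(
    config: ModelConfig, strategy: str, rng: np.random.Generator, production_cost_mode: str
) -> dict[str, float]:
    herd = config.herd_size
    policy = build_policy(strategy, config)
    cure_trim = config.prob("cure_probability_trim")
    cure_notrim = config.prob("cure_probability_no_trim")
    onset = config.onset_probability()
    prod_unit = config.cost(
        "additional_cow_cost" if production_cost_mode == "additional_cow" else "milk_loss_cost"
    )

    ulcer = rng.random(herd) < config.prob("prevalence")

    n_cycles = config.n_cycles
    trims_k = np.zeros(n_cycles)
    ulcer_trims_k = np.zeros(n_cycles)
    ulcer_k = np.zeros(n_cycles)
    for k in range(n_cycles):
        p_u, p_h = policy.pairs[k]
        p_trim = np.where(ulcer, p_u, p_h)
        trimmed = rng.random(herd) < p_trim
        trims_k[k] = trimmed.sum()
        ulcer_trims_k[k] = (trimmed & ulcer).sum()
        ulcer_k[k] = ulcer.sum()

        p_cure = np.where(trimmed, cure_trim, cure_notrim)
        cured = ulcer & (rng.random(herd) < p_cure)
        ulcer = ulcer & ~cured
        new = ~ulcer & (rng.random(herd) < onset)
        ulcer = ulcer | new

    if strategy == "partial":
        labor_k = np.full(n_cycles, config.cost("labor_partial"))
    else:
        labor_k = np.array(
            [
                config.cost("labor_whole") if k % config.whole_herd_interval == 0 else 0.0
                for k in range(n_cycles)
            ]
        )
    healthy_k = herd - ulcer_k
    streams = {
        "trim_cost": trims_k * config.cost("trim_cost"),
        "block_cost": ulcer_trims_k * config.cost("block_cost"),
        "reproduction_cost": (
            ulcer_k * config.cost("ai_cost_ulcer") + healthy_k * config.cost("ai_cost_no_ulcer")
        )
        / config.cycles_per_year,
        "labor_cost": labor_k,
        "su_production_cost": ulcer_k * prod_unit,
    }
    per_cycle_total = sum(streams.values())
    tallies = {
        "trims": float(trims_k.sum()),
        "ulcer_trims": float(ulcer_trims_k.sum()),
        "ulcer_cow_cycles": float(ulcer_k.sum()),
        "total_discounted": discount_yearly(
            _yearly_sums(per_cycle_total, config.cycles_per_year), config.discount_rate
        ),
    }
    tallies.update({name: float(s.sum()) for name, s in streams.items()})
    return tallies


def simulate_herd(
    config: ModelConfig,
    strategy: str,
    seed: int,
    production_cost_mode: str = "additional_cow",
) -> MicrosimResult:
    """One realized herd history; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tallies = _simulate_arm(config, strategy, rng, production_cost_mode)
    return MicrosimResult(
        strategy=strategy, tallies=tallies, standard_errors=None, n_replicates=1, seed=seed
    )


def replicate_mean(
    config: ModelConfig,
    strategy: str,
    n_reps: int,
    seed: int,
    production_cost_mode: str = "additional_cow",
) -> MicrosimResult:
    """Mean and standard error of the tallies over independent replicates.

    Replicate RNG streams are spawned from the master seed, so the result
    does not depend on execution order.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    samples = {name: np.empty(n_reps) for name in TALLIES}
    for i in range(n_reps):
        tallies = _simulate_arm(
            config, strategy, np.random.default_rng(children[i]), production_cost_mode
        )
        for name in TALLIES:
            samples[name][i] = tallies[name]
    means = {name: float(v.mean()) for name, v in samples.items()}
    ses = {name: float(v.std(ddof=1) / np.sqrt(n_reps)) for name, v in samples.items()}
    return MicrosimResult(
        strategy=strategy, tallies=means, standard_errors=ses, n_replicates=n_reps, seed=seed
    )


def _cohort_expectations(
    config: ModelConfig, strategy: str, production_cost_mode: str
) -> dict[str, float]:
    trace = run_cohort(config, strategy)
    breakdown = accrue_costs(trace, config, strategy, production_cost_mode)
    out = {
        "trims": trace.expected_trims_total,
        "ulcer_trims": trace.expected_ulcer_trims_total,
        "ulcer_cow_cycles": trace.expected_ulcer_cow_cycles,
        "total_discounted": breakdown.total_discounted,
    }
    out.update({name: breakdown.component(name) for name in COMPONENTS})
    return out


def validate_against_cohort(
    config: ModelConfig,
    n_reps: int,
    seed: int,
    tolerance_se: float = 3.0,
    production_cost_mode: str = "additional_cow",
) -> pd.DataFrame:
    """Check every cohort expectation against the microsimulation replicate mean.

    Returns one row per (arm, quantity) with the cohort expectation, the
    replicate mean, its standard error, the z-score and a pass flag:
    |mean - expectation| <= tolerance_se x SE (exact agreement required where
    the SE is zero, e.g. the whole-herd trim count).
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    rows = []
    for arm_index, strategy in enumerate(("partial", "whole")):
        expected = _cohort_expectations(config, strategy, production_cost_mode)
        sim = replicate_mean(config, strategy, n_reps, seed + arm_index, production_cost_mode)
        for name in TALLIES:
            mean, se = sim.tallies[name], sim.standard_errors[name]
            delta = mean - expected[name]
            # absolute floor handles deterministic tallies, whose SE is zero
            # (or rounding noise) and whose agreement must be exact
            atol = 1e-9 * max(1.0, abs(expected[name]))
            z = delta / se if se > 0 else 0.0
            ok = abs(delta) <= max(tolerance_se * se, atol)
            rows.append((strategy, name, expected[name], mean, se, z, bool(ok)))
    return pd.DataFrame(
        rows,
        columns=["strategy", "quantity", "cohort_value", "microsim_mean", "se", "z", "passed"],
    )
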