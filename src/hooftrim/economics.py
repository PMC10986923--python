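"""Cost accrual, benefits, discounting, and the strategy comparison.

Accrual rules, all per 2-month cycle from the cohort trace:

* trim cost        = expected trims x price per trim
* block cost       = expected ulcer-trims x expected block cost per ulcer trim
* labor            = one sorting-labor charge per partial session (every cycle)
                     or per whole-herd session (session cycles only); labor is
                     per session, not per cow
* reproduction     = herd x [s x AI-with-ulcer + (1-s) x AI-without-ulcer] / 6
                     (annual AI cost spread evenly over the 6 cycles per year,
                     conditional on ulcer state at cycle start)
* production loss  = ulcer cow-cycles x unit cost; the unit is the fractional
                     additional cow needed to fill the milk quota
                     (reference case) or the direct milk loss (non-quota
                     scenario) — never both

Components are reported undiscounted; the total is additionally reported
discounted, with per-year sums (6 cycles per model year) weighted by
1/(1+r)^y for y = 0, 1, 2.  Benefits (milk plus net cattle sales) are the
same in both arms, so the net-benefit difference reduces to the discounted
cost gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CohortTrace, run_cohort
from .parameters import ModelConfig

__all__ = [
    "CostBreakdown",
    "NetBenefitResult",
    "PRODUCTION_COST_MODES",
    "accrue_costs",
    "annual_benefits",
    "discounted_benefits",
    "discount_yearly",
    "compare_strategies",
]

PRODUCTION_COST_MODES = ("additional_cow", "milk_loss")

COMPONENTS = ("trim_cost", "block_cost", "reproduction_cost", "labor_cost", "su_production_cost")


@dataclass(frozen=True)
class CostBreakdown:
    """Five cost components (undiscounted) plus totals for one strategy arm."""

    trim_cost: float
    block_cost: float
    reproduction_cost: float
    labor_cost: float
    su_production_cost: float
    total_undiscounted: float
    total_discounted: float

    def component(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class NetBenefitResult:
    """Both arms' costs, the shared benefits, and the net-benefit difference."""

    benefits_discounted: float
    cost_partial: CostBreakdown
    cost_whole: CostBreakdown
    net_benefit_partial: float
    net_benefit_whole: float
    difference: float  # partial minus whole; positive favors partial


def discount_yearly(values_per_year: Sequence[float], rate: float) -> float:
    """Present value of beginning-of-year cash flows at an annual rate."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return float(sum(v / (1.0 + rate) ** y for y, v in enumerate(values_per_year)))


def _yearly_sums(per_cycle: np.ndarray, cycles_per_year: int) -> np.ndarray:
    """Group a per-cycle cash-flow stream into model-year sums."""
    n = len(per_cycle)
    n_years = -(-n // cycles_per_year)  # ceil; last year may be partial
    out = np.zeros(n_years)
    for k, v in enumerate(per_cycle):
        out[k // cycles_per_year] += v
    return out


def per_cycle_costs(
    trace: CohortTrace,
    config: ModelConfig,
    strategy: str,
    production_cost_mode: str = "additional_cow",
) -> dict[str, np.ndarray]:
    """Per-cycle cash-flow streams for the five cost components."""
    if production_cost_mode not in PRODUCTION_COST_MODES:
        raise ValueError(
            f"unknown production_cost_mode {production_cost_mode!r}; "
            f"expected one of {PRODUCTION_COST_MODES}"
        )
    if trace.n_cycles != config.n_cycles:
        raise ValueError(
            f"trace has {trace.n_cycles} cycles but config expects {config.n_cycles}"
        )
    herd = trace.herd_size
    cycles_per_year = config.cycles_per_year
    prod_unit = config.cost(
        "additional_cow_cost" if production_cost_mode == "additional_cow" else "milk_loss_cost"
    )

    trimmed = np.array([o.frac_trimmed for o in trace.occupancies])
    trimmed_ulcer = np.array([o.frac_trimmed_ulcer for o in trace.occupancies])
    s_start = np.array([o.s_start for o in trace.occupancies])

    if strategy == "partial":
        labor = np.full(trace.n_cycles, config.cost("labor_partial"))
    elif strategy == "whole":
        labor = np.array(
            [
                config.cost("labor_whole") if k % config.whole_herd_interval == 0 else 0.0
                for k in range(trace.n_cycles)
            ]
        )
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    return {
        "trim_cost": herd * trimmed * config.cost("trim_cost"),
        "block_cost": herd * trimmed_ulcer * config.cost("block_cost"),
        "reproduction_cost": herd
        * (s_start * config.cost("ai_cost_ulcer") + (1.0 - s_start) * config.cost("ai_cost_no_ulcer"))
        / cycles_per_year,
        "labor_cost": labor,
        "su_production_cost": herd * s_start * prod_unit,
    }


def accrue_costs(
    trace: CohortTrace,
    config: ModelConfig,
    strategy: str,
    production_cost_mode: str = "additional_cow",
) -> CostBreakdown:
    """Aggregate the per-cycle streams into one arm's cost breakdown."""
    streams = per_cycle_costs(trace, config, strategy, production_cost_mode)
    totals = {name: float(stream.sum()) for name, stream in streams.items()}
    per_cycle_total = sum(streams.values())
    yearly = _yearly_sums(per_cycle_total, config.cycles_per_year)
    return CostBreakdown(
        **totals,
        total_undiscounted=float(per_cycle_total.sum()),
        total_discounted=discount_yearly(yearly, config.discount_rate),
    )


def annual_benefits(config: ModelConfig) -> float:
    """Herd-level benefits per year: milk sales plus net cattle sales."""
    return config.herd_size * (config.cost("milk_sales") + config.cost("cattle_sales"))


def discounted_benefits(config: ModelConfig) -> float:
    """Present value of the horizon's annual benefits (same in both arms)."""
    annual = annual_benefits(config)
    cycles_per_year = config.cycles_per_year
    n_full, remainder = divmod(config.n_cycles, cycles_per_year)
    values = [annual] * n_full
    if remainder:
        values.append(annual * remainder / cycles_per_year)
    return discount_yearly(values, config.discount_rate)


def compare_strategies(
    config: ModelConfig, production_cost_mode: str = "additional_cow"
) -> NetBenefitResult:
    """Deterministic net-benefit comparison of the two trimming strategies."""
    benefits = discounted_benefits(config)
    cost_partial = accrue_costs(
        run_cohort(config, "partial"), config, "partial", production_cost_mode
    )
    cost_whole = accrue_costs(
        run_cohort(config, "whole"), config, "whole", production_cost_mode
    )
    nb_partial = benefits - cost_partial.total_discounted
    nb_whole = benefits - cost_whole.total_discounted
    return NetBenefitResult(
        benefits_discounted=benefits,
        cost_partial=cost_partial,
        cost_whole=cost_whole,
        net_benefit_partial=nb_partial,
        net_benefit_whole=nb_whole,
        difference=nb_partial - nb_whole,
    )
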