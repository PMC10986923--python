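"""Markov cohort engine: expected compartment occupancy per 2-month cycle.

Each cycle a cow is in one of four outcomes — trimmed/ulcer, trimmed/healthy,
untrimmed/ulcer, untrimmed/healthy — determined by its ulcer state at the
cycle start and the strategy's selection probabilities.  The within-cycle
event order is pinned as select -> cure -> onset: selection must precede cure
because the cure probability is conditional on being trimmed (0.85) or not
(0.20), and applying onset last lets a cow cured this cycle relapse, keeping
the process memoryless.  Ulcer state is counted for cost accrual at cycle
start, before cure: a cow trimmed for its ulcer still incurs that ulcer's
costs (block, lost production) in the same cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .parameters import ModelConfig

__all__ = [
    "TrimPolicy",
    "CycleOccupancy",
    "CohortTrace",
    "build_policy",
    "step_cycle",
    "run_cohort",
    "expected_trims",
    "trace_to_frame",
]

STRATEGIES = ("partial", "whole")


@dataclass(frozen=True)
class TrimPolicy:
    """Per-cycle selection probabilities (P(trim | ulcer), P(trim | healthy))."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for k, (pu, ph) in enumerate(self.pairs):
            if not (0.0 <= pu <= 1.0 and 0.0 <= ph <= 1.0):
                raise ValueError(f"cycle {k}: policy pair ({pu}, {ph}) outside [0, 1]")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class CycleOccupancy:
    """Expected fractions of the herd in the four outcomes for one cycle."""

    cycle_index: int
    frac_trimmed_ulcer: float
    frac_trimmed_healthy: float
    frac_untrimmed_ulcer: float
    frac_untrimmed_healthy: float
    s_start: float  # ulcer prevalence at cycle start (accrual basis)
    s_end: float  # prevalence after cure and onset

    @property
    def frac_trimmed(self) -> float:
        return self.frac_trimmed_ulcer + self.frac_trimmed_healthy


@dataclass(frozen=True)
class CohortTrace:
    """Full occupancy history plus the event totals cost accrual needs."""

    occupancies: tuple[CycleOccupancy, ...]
    herd_size: int
    expected_trims_total: float
    expected_ulcer_trims_total: float
    expected_ulcer_cow_cycles: float

    @property
    def n_cycles(self) -> int:
        return len(self.occupancies)


def build_policy(strategy: str, config: ModelConfig) -> TrimPolicy:
    """Selection schedule for one strategy arm.

    ``partial``: every cycle uses the config's two conditional selection
    probabilities.  ``whole``: every cow is trimmed (probability 1 for both
    states) at session cycles 0, interval, 2*interval, ... and nobody is
    trimmed in between — for 18 cycles at interval 3 this gives exactly six
    whole-herd sessions.
    """
    if strategy == "partial":
        pair = (
            config.prob(config.policy_ulcer_param),
            config.prob(config.policy_healthy_param),
        )
        return TrimPolicy(tuple(pair for _ in range(config.n_cycles)))
    if strategy == "whole":
        pairs = tuple(
            (1.0, 1.0) if k % config.whole_herd_interval == 0 else (0.0, 0.0)
            for k in range(config.n_cycles)
        )
        return TrimPolicy(pairs)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def step_cycle(
    s_start: float,
    policy_pair: tuple[float, float],
    cure_trim: float,
    cure_notrim: float,
    onset: float,
    cycle_index: int = 0,
) -> CycleOccupancy:
    """Advance the cohort one cycle under the pinned select -> cure -> onset order."""
    p_trim_u, p_trim_h = policy_pair
    for label, v in (
        ("s_start", s_start),
        ("p_trim_ulcer", p_trim_u),
        ("p_trim_healthy", p_trim_h),
        ("cure_trim", cure_trim),
        ("cure_notrim", cure_notrim),
        ("onset", onset),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{label} = {v} outside [0, 1]")

    tu = s_start * p_trim_u
    uu = s_start * (1.0 - p_trim_u)
    th = (1.0 - s_start) * p_trim_h
    uh = (1.0 - s_start) * (1.0 - p_trim_h)

    surviving = tu * (1.0 - cure_trim) + uu * (1.0 - cure_notrim)
    healthy_after_cure = 1.0 - surviving
    s_end = surviving + healthy_after_cure * onset

    return CycleOccupancy(
        cycle_index=cycle_index,
        frac_trimmed_ulcer=tu,
        frac_trimmed_healthy=th,
        frac_untrimmed_ulcer=uu,
        frac_untrimmed_healthy=uh,
        s_start=s_start,
        s_end=s_end,
    )


def run_cohort(config: ModelConfig, strategy: str) -> CohortTrace:
    """Evolve expected occupancy from the starting prevalence for n_cycles."""
    policy = build_policy(strategy, config)
    cure_trim = config.prob("cure_probability_trim")
    cure_notrim = config.prob("cure_probability_no_trim")
    onset = config.onset_probability()

    s = config.prob("prevalence")
    occupancies: list[CycleOccupancy] = []
    for k in range(config.n_cycles):
        occ = step_cycle(s, policy.pairs[k], cure_trim, cure_notrim, onset, cycle_index=k)
        occupancies.append(occ)
        s = occ.s_end

    herd = config.herd_size
    return CohortTrace(
        occupancies=tuple(occupancies),
        herd_size=herd,
        expected_trims_total=herd * sum(o.frac_trimmed for o in occupancies),
        expected_ulcer_trims_total=herd * sum(o.frac_trimmed_ulcer for o in occupancies),
        expected_ulcer_cow_cycles=herd * sum(o.s_start for o in occupancies),
    )


def expected_trims(trace: CohortTrace) -> float:
    """Total expected cow-trimmings, re-derived from the occupancy sequence."""
    total = trace.herd_size * sum(o.frac_trimmed for o in trace.occupancies)
    if abs(total - trace.expected_trims_total) > 1e-9 * max(1.0, total):
        raise ValueError("trace totals inconsistent with occupancy sequence")
    return total


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Tidy per-cycle export of the occupancy trace (one row per cycle)."""
    return pd.DataFrame(
        {
            "cycle_index": [o.cycle_index for o in trace.occupancies],
            "frac_trimmed_ulcer": [o.frac_trimmed_ulcer for o in trace.occupancies],
            "frac_trimmed_healthy": [o.frac_trimmed_healthy for o in trace.occupancies],
            "frac_untrimmed_ulcer": [o.frac_untrimmed_ulcer for o in trace.occupancies],
            "frac_untrimmed_healthy": [o.frac_untrimmed_healthy for o in trace.occupancies],
            "s_start": [o.s_start for o in trace.occupancies],
            "s_end": [o.s_end for o in trace.occupancies],
        }
    )
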