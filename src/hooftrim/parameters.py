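"""Model inputs: probabilities, costs, structural constants, and their transforms.

The decision model compares two hoof-trimming strategies for managing sole
ulcers (SU) in a closed 100-cow dairy herd over a 36-month horizon of
2-month cycles: *partial-herd* trimming (a targeted subset every cycle) versus
*whole-herd* trimming (every cow, every third cycle).  All inputs are scalar
parameters: probabilities with Beta uncertainty distributions
(events = alpha, non-events = beta) and 2019 prices with Normal uncertainty
on the Canadian-dollar mean, converted to USD at a fixed exchange rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ProbabilityParam",
    "MoneyParam",
    "SensitivityBound",
    "ModelConfig",
    "ConfigError",
    "reference_parameters",
    "load_config",
    "rate_from_risk",
    "cycle_probability_from_rate",
    "beta_mean",
    "usd_from_cad",
    "FX_RATE",
]

#: 2019 exchange rate: CAN$1 = US$0.77.
FX_RATE = 0.77


class ConfigError(ValueError):
    """Raised when a configuration value violates a model invariant."""


@dataclass(frozen=True)
class ProbabilityParam:
    """A probability input with an optional Beta uncertainty distribution.

    ``alpha`` counts events and ``beta_`` non-events; both must be positive
    when a distribution is defined.  A parameter without a distribution is
    held fixed in the probabilistic analysis.
    """

    name: str
    value: float
    alpha: float | None = None
    beta_: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ConfigError(f"{self.name}: probability {self.value} outside [0, 1]")
        if (self.alpha is None) != (self.beta_ is None):
            raise ConfigError(f"{self.name}: alpha and beta_ must be given together")
        if self.alpha is not None and (self.alpha <= 0 or self.beta_ <= 0):
            raise ConfigError(f"{self.name}: Beta shapes must be positive")

    @property
    def has_distribution(self) -> bool:
        return self.alpha is not None


@dataclass(frozen=True)
class MoneyParam:
    """A price input in 2019 USD, sampled as Normal(cad_mean, cad_sd) x fx.

    The model keeps all accounting in USD; the CAD mean and sd describe the
    sampling distribution used in the probabilistic analysis.
    """

    name: str
    usd_value: float
    cad_mean: float
    cad_sd: float = 0.1
    source: str = ""

    def __post_init__(self) -> None:
        if self.usd_value < 0:
            raise ConfigError(f"{self.name}: negative cost {self.usd_value}")
        if self.cad_sd < 0:
            raise ConfigError(f"{self.name}: negative sd {self.cad_sd}")


@dataclass(frozen=True)
class SensitivityBound:
    """Low/high limits for one input of the one-way sensitivity analysis."""

    param_name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ConfigError(f"{self.param_name}: low {self.low} > high {self.high}")


@dataclass(frozen=True)
class ModelConfig:
    """Every input of the decision model.

    ``probabilities`` and ``costs`` are keyed by the snake_case parameter
    names used throughout the package (and in config files).  The partial
    policy reads its two per-cycle selection probabilities through
    ``policy_ulcer_param`` / ``policy_healthy_param``, which lets scenario
    analyses redirect both at a single shared parameter.
    """

    herd_size: int = 100
    n_cycles: int = 18
    cycle_months: int = 2
    discount_rate: float = 0.015
    fx_rate: float = FX_RATE
    probabilities: Mapping[str, ProbabilityParam] = field(default_factory=dict)
    costs: Mapping[str, MoneyParam] = field(default_factory=dict)
    block_price: float = 28.88  # full price of one orthopedic block, USD
    whole_herd_interval: int = 3  # whole-herd sessions every this many cycles
    psa_iterations: int = 2000
    seed: int = 0
    policy_ulcer_param: str = "trim_probability_ulcer"
    policy_healthy_param: str = "trim_probability_healthy"

    def __post_init__(self) -> None:
        if self.herd_size < 1:
            raise ConfigError(f"herd_size must be >= 1, got {self.herd_size}")
        if self.n_cycles < 1:
            raise ConfigError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ConfigError(f"discount_rate must be in [0, 1), got {self.discount_rate}")
        if self.whole_herd_interval < 1:
            raise ConfigError("whole_herd_interval must be >= 1")

    # -- convenience accessors -------------------------------------------------

    def prob(self, name: str) -> float:
        return self.probabilities[name].value

    def cost(self, name: str) -> float:
        return self.costs[name].usd_value

    @property
    def cycles_per_year(self) -> int:
        return 12 // self.cycle_months

    def onset_probability(self) -> float:
        """Per-cycle probability of developing a sole ulcer.

        Derived from the annual incidence risk via the risk->rate->cycle
        probability chain so that a resampled risk propagates consistently.
        """
        rate = rate_from_risk(self.prob("incidence_risk"))
        return cycle_probability_from_rate(rate, self.cycle_months / 12.0)

    def with_probability(self, name: str, value: float) -> "ModelConfig":
        """Copy of the config with one probability value replaced."""
        probs = dict(self.probabilities)
        probs[name] = replace(probs[name], value=value)
        return replace(self, probabilities=probs)

    def with_cost(self, name: str, usd_value: float) -> "ModelConfig":
        """Copy with one USD cost replaced (CAD mean rescaled to match)."""
        costs = dict(self.costs)
        costs[name] = replace(
            costs[name], usd_value=usd_value, cad_mean=usd_value / self.fx_rate
        )
        return replace(self, costs=costs)


# -- analytic transforms -------------------------------------------------------


def rate_from_risk(risk: float) -> float:
    """Convert an incidence risk over one period to the equivalent rate.

    Assumes a constant hazard over the period: rate = -ln(1 - risk).
    """
    if not 0.0 <= risk < 1.0:
        raise ValueError(f"risk must be in [0, 1), got {risk}")
    return -math.log1p(-risk)


def cycle_probability_from_rate(rate: float, cycle_fraction: float) -> float:
    """Probability of at least one event in a fraction of the rate's period.

    1 - exp(-rate * cycle_fraction); with ``cycle_fraction = 1/6`` this turns
    an annual incidence rate into the 2-month onset probability.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if not 0.0 < cycle_fraction <= 1.0:
        raise ValueError(f"cycle_fraction must be in (0, 1], got {cycle_fraction}")
    return -math.expm1(-rate * cycle_fraction)


def beta_mean(alpha: float, beta_: float) -> float:
    """Mean alpha / (alpha + beta_) of a Beta distribution."""
    if alpha <= 0 or beta_ <= 0:
        raise ValueError("Beta shapes must be positive")
    return alpha / (alpha + beta_)


def usd_from_cad(amount: float, fx_rate: float = FX_RATE) -> float:
    """Convert 2019 CAD to 2019 USD at the model's fixed exchange rate."""
    return amount * fx_rate


# -- reference configuration ---------------------------------------------------


def reference_parameters() -> ModelConfig:
    """The reference-case configuration: every published input at face value.

    Two CAD means in the cost table are corrected as typographical errors
    (block 2.63 -> 26.30, AI-with-ulcer 886.75 -> 286.75); with these
    corrections every cost satisfies usd = cad_mean x 0.77.  The printed
    block cost of US$20.25 is the *expected* block cost per ulcer trim
    (price US$28.88 x application probability 0.70), so the 70% probability
    is never applied a second time during accrual.
    """
    probabilities = {
        "prevalence": ProbabilityParam(
            "prevalence", 0.064, 1830.0, 26777.0, source="Alberta trim records"
        ),
        "trim_probability_overall": ProbabilityParam(
            "trim_probability_overall", 0.18, 43.74, 199.26,
            source="fraction of herd trimmed per partial session",
        ),
        "trim_probability_ulcer": ProbabilityParam(
            "trim_probability_ulcer", 0.54, 853.7, 727.3,
            source="lameness-based selection of SU cows",
        ),
        "trim_probability_healthy": ProbabilityParam(
            "trim_probability_healthy", 0.1699, 16.99, 83.01,
            source="selection of cows without SU",
        ),
        "cure_probability_trim": ProbabilityParam(
            "cure_probability_trim", 0.85, 2927.4, 516.6,
            source="cure between trims when trimmed",
        ),
        "cure_probability_no_trim": ProbabilityParam(
            "cure_probability_no_trim", 0.20, 20.0, 80.0,
            source="spontaneous cure, expert opinion",
        ),
        "incidence_risk": ProbabilityParam(
            "incidence_risk", 0.078, 465.0, 1624.7, source="annual SU incidence risk"
        ),
        "block_probability": ProbabilityParam(
            "block_probability", 0.70, source="block applied at an ulcer trim"
        ),
    }
    costs = {
        "milk_sales": MoneyParam("milk_sales", 6320.50, 8208.44, source="per cow-year"),
        "cattle_sales": MoneyParam("cattle_sales", 284.60, 369.60, source="per cow-year"),
        "trim_cost": MoneyParam("trim_cost", 15.02, 19.50, source="one trim, Alberta 2019"),
        "block_cost": MoneyParam(
            "block_cost", 20.25, 26.30, source="expected block cost per ulcer trim"
        ),
        "ai_cost_no_ulcer": MoneyParam(
            "ai_cost_no_ulcer", 132.48, 172.05, source="3 AI services per cow-year"
        ),
        "ai_cost_ulcer": MoneyParam(
            "ai_cost_ulcer", 220.80, 286.75, source="5 AI services per cow-year"
        ),
        "labor_partial": MoneyParam(
            "labor_partial", 13.34, 17.33, source="45 min sorting per partial session"
        ),
        "labor_whole": MoneyParam(
            "labor_whole", 2.96, 3.85, source="10 min per whole-herd session"
        ),
        "additional_cow_cost": MoneyParam(
            "additional_cow_cost", 101.63, 131.99,
            source="5% of a replacement cow per ulcer cow-cycle (quota system)",
        ),
        "milk_loss_cost": MoneyParam(
            "milk_loss_cost", 73.50, 95.46, source="milk loss per 2-month interval"
        ),
    }
    return ModelConfig(probabilities=probabilities, costs=costs)


def validate_fx_consistency(config: ModelConfig, tolerance: float = 0.005) -> None:
    """Check usd = cad_mean x fx_rate for every cost, to ``tolerance`` relative."""
    for p in config.costs.values():
        expected = p.cad_mean * config.fx_rate
        if expected == 0 and p.usd_value == 0:
            continue
        if abs(p.usd_value - expected) > tolerance * max(abs(expected), 1e-12):
            raise ConfigError(
                f"{p.name}: usd {p.usd_value} inconsistent with "
                f"cad {p.cad_mean} x {config.fx_rate} = {expected:.4f}"
            )


# -- config files --------------------------------------------------------------

_STRUCTURAL_KEYS = {
    "herd_size": int,
    "n_cycles": int,
    "cycle_months": int,
    "discount_rate": float,
    "fx_rate": float,
    "block_price": float,
    "whole_herd_interval": int,
    "psa_iterations": int,
    "seed": int,
}


def load_config(path: str | Path) -> ModelConfig:
    """Load a flat YAML config; unspecified keys default to the reference case.

    Probability keys set the parameter's deterministic value (its Beta shapes
    are kept); cost keys set the USD value and rescale the CAD mean to match.
    Unknown keys, out-of-range probabilities and negative costs raise
    :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file must be a mapping, got {type(raw).__name__}")

    config = reference_parameters()
    structural: dict[str, object] = {}
    for key, value in raw.items():
        if key in _STRUCTURAL_KEYS:
            structural[key] = _STRUCTURAL_KEYS[key](value)
        elif key in config.probabilities:
            if not isinstance(value, (int, float)) or not 0.0 <= value <= 1.0:
                raise ConfigError(f"{key}: probability {value!r} outside [0, 1]")
            config = config.with_probability(key, float(value))
        elif key in config.costs:
            if not isinstance(value, (int, float)) or value < 0:
                raise ConfigError(f"{key}: cost {value!r} must be >= 0")
            config = config.with_cost(key, float(value))
        else:
            raise ConfigError(f"unknown config key: {key}")
    if structural:
        config = replace(config, **structural)
    return config
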