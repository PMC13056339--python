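"""Stability-anchored counterfactual distributions over worlds.

Counterfactual sampling proceeds per variable: with probability ``s`` (the
stability) a variable keeps the value it had in the actual world, and with
probability ``1 - s`` it is resampled from its prior.  The two stages
collapse into a single mixture propensity per variable and value,

    P(V = v) = s * 1[v = v_actual] + (1 - s) * (prior if v = 1 else 1 - prior),

which makes the full distribution over worlds a product measure that can be
enumerated exactly for moderate ``n``.  Exact enumeration is the default
scoring path; Monte-Carlo sampling mirrors the simulation procedure and
serves as a stochastic cross-check.

Variables flagged as unanchored (``VariableSpec.anchored == False``) ignore
``s`` entirely and are always drawn fresh from their prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .scenario import CausalScenario, ScenarioError, World, world_matrix

__all__ = [
    "SamplerConfig",
    "CounterfactualDistribution",
    "WorldSample",
    "value_propensity",
    "propensity_vector",
    "enumerate_distribution",
    "sample_worlds",
]

MAX_ENUM_VARIABLES = 20


@dataclass(frozen=True)
class SamplerConfig:
    """Stability plus Monte-Carlo settings.

    ``seed`` is mandatory for any sampling path; exact enumeration ignores it.
    """

    s: float
    n_samples: int = 100_000
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"stability s must lie in [0, 1], got {self.s}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def value_propensity(prior: float, actual_value: int, value: int, s: float) -> float:
    """Per-variable sampling propensity of ``value`` given the actual value.

    ``s * 1[value == actual] + (1 - s) * (prior if value == 1 else 1 - prior)``.
    The propensities of the two values sum to one.
    """
    if not 0.0 <= prior <= 1.0:
        raise ValueError("prior must lie in [0, 1]")
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    if actual_value not in (0, 1) or value not in (0, 1):
        raise ValueError("values must be 0 or 1")
    base = prior if value == 1 else 1.0 - prior
    return s * float(value == actual_value) + (1.0 - s) * base


def propensity_vector(scenario: CausalScenario, actual: World, s: float) -> np.ndarray:
    """P(V = 1) per variable, in scenario order; unanchored variables use their prior."""
    priors = scenario.priors
    actual_values = actual.values_for(scenario.names).astype(float)
    anchored = scenario.anchored_mask
    p1 = s * actual_values + (1.0 - s) * priors
    return np.where(anchored, p1, priors)


@dataclass
class CounterfactualDistribution:
    """The exact propensity-weighted distribution over all ``2**n`` worlds."""

    scenario: CausalScenario
    worlds: np.ndarray  # (2**n, n) uint8, columns in scenario.names order
    probabilities: np.ndarray  # (2**n,) floats summing to 1
    outcomes: np.ndarray  # (2**n,) uint8
    s: float

    def marginal(self, name: str) -> float:
        """P(V = 1) under the distribution."""
        j = self.scenario.index(name)
        return float(self.probabilities @ (self.worlds[:, j] == 1))

    def outcome_probability(self) -> float:
        return float(self.probabilities @ self.outcomes)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.worlds, columns=list(self.scenario.names))
        frame["probability"] = self.probabilities
        frame["outcome"] = self.outcomes
        return frame


@dataclass
class WorldSample:
    """I.i.d. draws from the counterfactual distribution."""

    scenario: CausalScenario
    worlds: np.ndarray  # (n_samples, n) uint8
    outcomes: np.ndarray  # (n_samples,) uint8
    config: SamplerConfig = field(repr=False)

    def __len__(self) -> int:
        return self.worlds.shape[0]


def enumerate_distribution(
    scenario: CausalScenario, actual: World, config: SamplerConfig
) -> CounterfactualDistribution:
    """Exact counterfactual distribution by full enumeration.

    Each world's probability is the product of per-variable value
    propensities; outcomes come from the scenario rule.  Guarded to
    ``n <= 20`` variables.
    """
    if scenario.n > MAX_ENUM_VARIABLES:
        raise ScenarioError(
            f"exact enumeration limited to {MAX_ENUM_VARIABLES} variables, "
            f"scenario has {scenario.n}"
        )
    worlds = world_matrix(scenario.n)
    p1 = propensity_vector(scenario, actual, config.s)
    per_var = np.where(worlds == 1, p1, 1.0 - p1)
    probabilities = per_var.prod(axis=1)
    return CounterfactualDistribution(
        scenario=scenario,
        worlds=worlds,
        probabilities=probabilities,
        outcomes=scenario.outcome_vector(),
        s=config.s,
    )


def sample_worlds(
    scenario: CausalScenario, actual: World, config: SamplerConfig
) -> WorldSample:
    """Draw ``config.n_samples`` i.i.d. counterfactual worlds (seed required)."""
    if config.seed is None:
        raise ValueError("sampling requires an explicit seed in SamplerConfig")
    rng = np.random.default_rng(config.seed)
    p1 = propensity_vector(scenario, actual, config.s)
    draws = (rng.random((config.n_samples, scenario.n)) < p1).astype(np.uint8)
    env = {name: draws[:, j] for j, name in enumerate(scenario.names)}
    outcomes = scenario.rule.evaluate(env)
    return WorldSample(scenario=scenario, worlds=draws, outcomes=outcomes, config=config)
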