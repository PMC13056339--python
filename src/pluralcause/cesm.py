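"""Counterfactual Effect Size Model (CESM) scores.

In flat binary structures the CESM reduces to the Pearson correlation
between the (possibly compound) cause indicator and the outcome across the
counterfactual distribution.  A plural cause is scored wholesale: its
indicator is 1 exactly when every literal holds, so "A and B" is treated as
one compound binary variable.

When either the indicator or the outcome is constant across worlds the
correlation is undefined; the score is 0 by convention, encoding "no
counterfactual dependence" (this covers the degenerate s = 1 point mass).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .counterfactual import (
    CounterfactualDistribution,
    SamplerConfig,
    enumerate_distribution,
    sample_worlds,
)
from .scenario import CandidateCause, CausalScenario, World

__all__ = ["CesmScore", "cesm_score", "weighted_correlation"]

_VAR_EPS = 1e-15


@dataclass(frozen=True)
class CesmScore:
    cause: CandidateCause
    score: float
    mode: str  # "exact" | "monte_carlo"


def weighted_correlation(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray
) -> float:
    """Probability-weighted Pearson correlation; 0 if either side is constant."""
    w = weights / weights.sum()
    x = x.astype(float)
    y = y.astype(float)
    mx = w @ x
    my = w @ y
    cov = w @ (x * y) - mx * my
    vx = w @ (x * x) - mx * mx
    vy = w @ (y * y) - my * my
    if vx <= _VAR_EPS or vy <= _VAR_EPS:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def cesm_score(
    scenario: CausalScenario,
    actual: World,
    cause: CandidateCause,
    config: SamplerConfig,
    mode: str = "exact",
    distribution: Optional[CounterfactualDistribution] = None,
) -> CesmScore:
    """Score ``cause`` by its correlation with the outcome across counterfactuals.

    ``mode="exact"`` uses full enumeration (deterministic); ``"monte_carlo"``
    uses the sample correlation over ``config.n_samples`` seeded draws.  A
    precomputed ``distribution`` may be passed to amortize enumeration across
    causes scored against the same (scenario, actual, s).
    """
    cause.validate(scenario)
    if mode == "exact":
        dist = distribution
        if dist is None:
            dist = enumerate_distribution(scenario, actual, config)
        x = cause.indicator(dist.worlds, scenario.names)
        r = weighted_correlation(x, dist.outcomes, dist.probabilities)
        return CesmScore(cause=cause, score=r, mode="exact")
    if mode == "monte_carlo":
        sample = sample_worlds(scenario, actual, config)
        x = cause.indicator(sample.worlds, scenario.names)
        w = np.ones(len(sample), dtype=float)
        r = weighted_correlation(x, sample.outcomes, w)
        return CesmScore(cause=cause, score=r, mode="monte_carlo")
    raise ValueError(f"unknown mode {mode!r}")
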