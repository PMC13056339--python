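"""Necessity-Sufficiency Model (NSM) scores for singular and plural causes.

Necessity asks: starting from the actual world, if the cause had not held,
would the outcome have gone away?  For a plural cause "not holding" means
any assignment of the cause's variables other than the required one, each
alternative weighted by its sampling propensity.  In the default
``fixed_at_actual`` mode every anchored off-candidate variable is held at
its actual value while the cause's variables are varied; in ``resampled``
mode off-candidate variables are marginalized by their propensities as well.
Unanchored variables (the loss-interpretation coin) are always marginalized.

Sufficiency asks: in counterfactual worlds where neither the cause nor the
outcome holds, would intervening to make the cause hold bring the outcome
about?  Worlds are drawn from the full propensity product measure,
conditioned on cause-absent and outcome-absent, and the cause's variables
are then forced to their required values.

The combined score is the convex combination

    prior(cause) * sufficiency + (1 - prior(cause)) * necessity,

so rare causes are judged mostly by necessity and common ones by
sufficiency.  Because a conjunction is never more probable than its
conjuncts, plural causes always tilt toward necessity.

Zero-mass conditioning sets (e.g. at the s = 1 boundary, where no
counterfactual deviates from actuality) yield a score of 0 by convention,
logged at warning level, so that parameter grids remain total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .counterfactual import SamplerConfig, enumerate_distribution
from .scenario import (
    CandidateCause,
    CausalScenario,
    ScenarioError,
    World,
    world_matrix,
)

__all__ = [
    "NsmScore",
    "necessity",
    "necessity_components",
    "sufficiency",
    "sufficiency_components",
    "nsm_score",
]

logger = logging.getLogger(__name__)

FIXED_AT_ACTUAL = "fixed_at_actual"
RESAMPLED = "resampled"


@dataclass(frozen=True)
class NsmScore:
    cause: CandidateCause
    necessity: float
    sufficiency: float
    prior: float
    combined: float
    off_candidate_mode: str


def _check_preconditions(
    scenario: CausalScenario, actual: World, cause: CandidateCause
) -> None:
    cause.validate(scenario)
    if not cause.holds_in(actual.assignment):
        raise ScenarioError(
            f"cause {cause.label!r} does not hold in the actual world"
        )
    if actual.outcome != 1:
        raise ScenarioError(
            "NSM scoring expects the outcome to be present in the actual world; "
            "score losses against a loss-outcome scenario"
        )


def _conditional_flip_probability(
    scenario: CausalScenario,
    actual: World,
    cause: CandidateCause,
    s: float,
    off_candidate_mode: str,
) -> Tuple[float, float]:
    """(flip probability, complement mass) under the mode's product measure."""
    names = list(scenario.names)
    cause_cols = [scenario.index(name) for name in cause.names]
    actual_values = actual.values_for(names).astype(float)
    priors = scenario.priors
    anchored = scenario.anchored_mask

    # Per-variable P(V=1) under the necessity measure.
    p1 = s * actual_values + (1.0 - s) * priors
    p1 = np.where(anchored, p1, priors)
    if off_candidate_mode == FIXED_AT_ACTUAL:
        fixed = anchored.copy()
        fixed[cause_cols] = False
        p1 = np.where(fixed, actual_values, p1)
    elif off_candidate_mode != RESAMPLED:
        raise ValueError(f"unknown off_candidate_mode {off_candidate_mode!r}")

    worlds = world_matrix(scenario.n)
    probs = np.where(worlds == 1, p1, 1.0 - p1).prod(axis=1)
    outcomes = scenario.outcome_vector()
    in_complement = cause.indicator(worlds, names) == 0
    mass = float(probs[in_complement].sum())
    if mass <= 0.0:
        return 0.0, 0.0
    flipped = float(probs[in_complement & (outcomes != actual.outcome)].sum())
    return flipped / mass, mass


def necessity_components(
    scenario: CausalScenario,
    actual: World,
    cause: CandidateCause,
    config: SamplerConfig,
    off_candidate_mode: str = FIXED_AT_ACTUAL,
) -> Tuple[float, float]:
    """Necessity score plus the normalizing mass of the cause-absent region."""
    _check_preconditions(scenario, actual, cause)
    score, mass = _conditional_flip_probability(
        scenario, actual, cause, config.s, off_candidate_mode
    )
    if mass == 0.0:
        logger.warning(
            "necessity of %s has a zero-mass complement region (s=%s); "
            "returning 0 by convention",
            cause.label,
            config.s,
        )
    return score, mass


def necessity(
    scenario: CausalScenario,
    actual: World,
    cause: CandidateCause,
    config: SamplerConfig,
    off_candidate_mode: str = FIXED_AT_ACTUAL,
) -> float:
    """Probability that removing the cause removes the outcome."""
    return necessity_components(scenario, actual, cause, config, off_candidate_mode)[0]


def sufficiency_components(
    scenario: CausalScenario,
    actual: World,
    cause: CandidateCause,
    config: SamplerConfig,
) -> Tuple[float, float]:
    """Sufficiency score plus the mass of the conditioning set."""
    _check_preconditions(scenario, actual, cause)
    dist = enumerate_distribution(scenario, actual, config)
    names = list(scenario.names)
    indicator = cause.indicator(dist.worlds, names)
    conditioning = (indicator == 0) & (dist.outcomes == 0)
    mass = float(dist.probabilities[conditioning].sum())
    if mass <= 0.0:
        logger.warning(
            "sufficiency of %s has a zero-mass conditioning set (s=%s); "
            "returning 0 by convention",
            cause.label,
            config.s,
        )
        return 0.0, 0.0
    # Intervene: force the cause's variables to their required values and
    # look the post-intervention world up in the enumerated outcome table.
    intervened = dist.worlds.copy()
    for name, value in cause.literals:
        intervened[:, scenario.index(name)] = value
    shifts = np.arange(scenario.n - 1, -1, -1)
    indices = (intervened.astype(np.int64) << shifts).sum(axis=1)
    post_outcomes = dist.outcomes[indices]
    produced = float(
        dist.probabilities[conditioning & (post_outcomes == 1)].sum()
    )
    return produced / mass, mass


def sufficiency(
    scenario: CausalScenario,
    actual: World,
    cause: CandidateCause,
    config: SamplerConfig,
) -> float:
    """Probability that adding the cause produces the outcome."""
    return sufficiency_components(scenario, actual, cause, config)[0]


def nsm_score(
    scenario: CausalScenario,
    actual: World,
    cause: CandidateCause,
    config: SamplerConfig,
    off_candidate_mode: str = FIXED_AT_ACTUAL,
) -> NsmScore:
    """Prior-weighted convex combination of sufficiency and necessity."""
    from .scenario import cause_prior

    nec = necessity(scenario, actual, cause, config, off_candidate_mode)
    suf = sufficiency(scenario, actual, cause, config)
    prior = cause_prior(cause, scenario)
    combined = prior * suf + (1.0 - prior) * nec
    return NsmScore(
        cause=cause,
        necessity=nec,
        sufficiency=suf,
        prior=prior,
        combined=combined,
        off_candidate_mode=off_candidate_mode,
    )
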