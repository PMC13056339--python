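"""Outcome semantics for losing rounds: classical vs. homogeneous negation.

When people explain a loss they may not score causes against the classical
negation of the winning rule.  The alternative modeled here mirrors the
homogeneity of natural-language plural negation ("the boys didn't do their
homework" = none of them did): the losing conditions become the conjunction
of the negations of exactly those events that were actually absent — the
strongest homogeneous negation that does not contradict the established
facts.  With all four urns empty-handed that is !A&!B&!C&!D; if a colored
ball actually came out of C, the strong rule drops C and reads !A&!B&!D.

The two readings are mixed by a weight ``w``: in each counterfactual world
an independent coin with bias ``w`` decides whether the world counts as a
loss under the strong rule (heads) or under the classical negation of the
winning rule (tails).  The coin is a fresh, never-anchored exogenous
variable, so the mixture is per-world, and ``w = 0`` recovers the classical
model exactly.  Scoring a losing round then runs the ordinary CESM/NSM
machinery on the augmented scenario with LOSS as the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .scenario import (
    CausalScenario,
    OutcomeRule,
    ScenarioError,
    VariableSpec,
    World,
    parse_rule,
)

__all__ = [
    "LossInterpretationConfig",
    "strong_loss_rule",
    "augment_with_interpretation",
    "INTERPRETATION_VARIABLE",
]

INTERPRETATION_VARIABLE = "NONCLASSICAL"


@dataclass(frozen=True)
class LossInterpretationConfig:
    """Probability ``w`` of reading the loss non-classically."""

    w: float

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")


def _require_loss(scenario: CausalScenario, actual: World) -> None:
    if actual.outcome != 0:
        raise ScenarioError(
            "the actual round is a win under the rule; loss semantics only "
            "apply to losing rounds"
        )


def strong_loss_rule(scenario: CausalScenario, actual: World) -> OutcomeRule:
    """Conjunction of !X over exactly the variables actually absent.

    This is the homogeneous ("none of them") negation of the winning
    conditions, restricted so as not to contradict what actually happened:
    variables that were present in the actual world are left out.
    """
    _require_loss(scenario, actual)
    absent = [name for name in scenario.names if actual[name] == 0]
    if not absent:
        raise ScenarioError(
            "no variable is absent in the actual world; the strong loss rule "
            "is undefined"
        )
    expression = "&".join(f"!{name}" for name in absent)
    return parse_rule(expression, scenario.names)


def augment_with_interpretation(
    scenario: CausalScenario,
    actual: World,
    config: LossInterpretationConfig,
    interpretation_name: str = INTERPRETATION_VARIABLE,
) -> Tuple[CausalScenario, World]:
    """Scenario whose outcome is LOSS under the w-mixture of negations.

    Adds one independent, never-anchored binary variable with prior ``w``
    (the per-world interpretation coin) and replaces the outcome with

        LOSS = coin ? strong_rule : !win_rule.

    Returns the augmented scenario together with the matching actual world
    (whose LOSS outcome is 1, since the round was actually lost either way).
    All CESM/NSM operations apply unchanged to the result.
    """
    _require_loss(scenario, actual)
    if interpretation_name in scenario.names:
        raise ScenarioError(
            f"variable name {interpretation_name!r} already exists in the scenario"
        )
    strong = strong_loss_rule(scenario, actual)
    win = scenario.rule.expression
    expression = (
        f"({interpretation_name}&({strong.expression}))"
        f"|(!{interpretation_name}&!({win}))"
    )
    variables = scenario.variables + (
        VariableSpec(interpretation_name, config.w, anchored=False),
    )
    rule = parse_rule(expression, [v.name for v in variables])
    label = (scenario.label + " [loss]").strip()
    augmented = CausalScenario(variables, rule, label=label)
    # The coin's "actual" value is irrelevant (never anchored); either value
    # leaves the actual round a loss.  Use 1 for definiteness.
    actual_assignment = dict(actual.assignment)
    actual_assignment[interpretation_name] = 1
    return augmented, augmented.world(actual_assignment)
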