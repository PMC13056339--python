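"""Canonical urn-game fixtures and end-to-end prediction tables.

Experiment 1: three urns (low/intermediate/high) with colored-ball
probabilities 0.05, 0.5 and 0.95; the player wins with two or more colored
balls.  One round is scored: all three balls colored (a win), with seven
questions — the three singular draws, the three pairs and the triple.

Experiment 2: four urns A, B, C, D with probabilities 0.7, 0.1, 0.2, 0.9
and the rule (A&B)|(C&D) — two sufficient conditions of two urns each.
Four rounds are scored: overdetermined positive (all colored),
triple positive (A, B, D colored), triple negative (only C colored, a loss)
and overdetermined negative (all white).  In winning rounds the questions
are positive literals over the drawn urns; in losing rounds they are
negative literals ("drew a white ball") over the white urns.  The default
question sets are exhaustive — all singulars, pairs and triples over the
queried literals, never the full four-variable plural.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cesm import cesm_score
from .counterfactual import SamplerConfig, enumerate_distribution
from .loss import LossInterpretationConfig, augment_with_interpretation
from .nsm import FIXED_AT_ACTUAL, nsm_score
from .scenario import (
    CandidateCause,
    CausalScenario,
    ScenarioError,
    VariableSpec,
    World,
    parse_rule,
)

__all__ = [
    "Round",
    "ExperimentSpec",
    "experiment1",
    "experiment2",
    "EXP2_ROUNDS",
    "prediction_table",
    "build_predictor",
]

EXP2_ROUNDS = (
    "overdetermined_positive",
    "triple_positive",
    "triple_negative",
    "overdetermined_negative",
)


@dataclass(frozen=True)
class Round:
    """One displayed outcome of the game plus the questions asked about it."""

    label: str
    actual: World
    polarity: str  # "win" | "loss"
    questions: Tuple[CandidateCause, ...]


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    scenario: CausalScenario
    rounds: Tuple[Round, ...]

    def round(self, label: str) -> Round:
        for rnd in self.rounds:
            if rnd.label == label:
                return rnd
        raise KeyError(f"unknown round {label!r}")

    @property
    def questions(self) -> List[Tuple[str, CandidateCause]]:
        """Flat (round label, cause) list in fixture order."""
        return [
            (rnd.label, cause) for rnd in self.rounds for cause in rnd.questions
        ]


def _conjunctions(
    names: Sequence[str], value: int, max_size: int
) -> Tuple[CandidateCause, ...]:
    causes = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(names, size):
            causes.append(CandidateCause({name: value for name in combo}))
    return tuple(causes)


def experiment1() -> ExperimentSpec:
    """Three-urn threshold game: priors 0.05/0.5/0.95, win on two or more."""
    variables = (
        VariableSpec("low", 0.05),
        VariableSpec("intermediate", 0.5),
        VariableSpec("high", 0.95),
    )
    names = [v.name for v in variables]
    rule = parse_rule("count(low,intermediate,high)>=2", names)
    scenario = CausalScenario(variables, rule, label="experiment 1")
    actual = scenario.world({"low": 1, "intermediate": 1, "high": 1})
    questions = _conjunctions(names, value=1, max_size=3)
    rounds = (Round("all_colored", actual, "win", questions),)
    return ExperimentSpec("exp1", scenario, rounds)


def _exp2_scenario() -> CausalScenario:
    variables = (
        VariableSpec("A", 0.7),
        VariableSpec("B", 0.1),
        VariableSpec("C", 0.2),
        VariableSpec("D", 0.9),
    )
    rule = parse_rule("(A&B)|(C&D)", [v.name for v in variables])
    return CausalScenario(variables, rule, label="experiment 2")


_EXP2_ACTUALS = {
    "overdetermined_positive": {"A": 1, "B": 1, "C": 1, "D": 1},
    "triple_positive": {"A": 1, "B": 1, "C": 0, "D": 1},
    "triple_negative": {"A": 0, "B": 0, "C": 1, "D": 0},
    "overdetermined_negative": {"A": 0, "B": 0, "C": 0, "D": 0},
}


def experiment2(round_label: Optional[str] = None) -> ExperimentSpec:
    """Four-urn disjunctive game; all four rounds or a single one.

    In each round the queried events follow the round's polarity: colored
    draws (positive literals) after a win, white draws (negative literals)
    after a loss.  Question sets are all singulars, pairs and triples over
    the queried literals.
    """
    scenario = _exp2_scenario()
    labels = EXP2_ROUNDS if round_label is None else (round_label,)
    rounds = []
    for label in labels:
        if label not in _EXP2_ACTUALS:
            raise KeyError(
                f"unknown round {label!r}; expected one of {EXP2_ROUNDS}"
            )
        actual = scenario.world(_EXP2_ACTUALS[label])
        win = actual.outcome == 1
        queried_value = 1 if win else 0
        queried = [
            name for name in scenario.names
            if actual[name] == queried_value
        ]
        questions = _conjunctions(queried, queried_value, max_size=3)
        rounds.append(
            Round(label, actual, "win" if win else "loss", questions)
        )
    return ExperimentSpec("exp2", scenario, tuple(rounds))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _scoring_context(
    scenario: CausalScenario, rnd: Round, w: float
) -> Tuple[CausalScenario, World]:
    """The (scenario, actual) pair the models score against for a round.

    Winning rounds score the win outcome directly; losing rounds score LOSS
    under the w-mixture of the strong and classical negations (w = 0 is the
    purely classical model).
    """
    if rnd.polarity == "win":
        return scenario, rnd.actual
    return augment_with_interpretation(
        scenario, rnd.actual, LossInterpretationConfig(w)
    )


def _score_round(
    scenario: CausalScenario,
    rnd: Round,
    model: str,
    s: float,
    w: float,
    off_candidate_mode: str = FIXED_AT_ACTUAL,
) -> List[dict]:
    config = SamplerConfig(s=s)
    scoring_scenario, scoring_actual = _scoring_context(scenario, rnd, w)
    rows = []
    if model == "cesm":
        dist = enumerate_distribution(scoring_scenario, scoring_actual, config)
        for cause in rnd.questions:
            score = cesm_score(
                scoring_scenario, scoring_actual, cause, config,
                distribution=dist,
            ).score
            rows.append({"cause": cause.label, "score": score})
    elif model == "nsm":
        for cause in rnd.questions:
            result = nsm_score(
                scoring_scenario, scoring_actual, cause, config,
                off_candidate_mode=off_candidate_mode,
            )
            rows.append(
                {
                    "cause": cause.label,
                    "score": result.combined,
                    "necessity": result.necessity,
                    "sufficiency": result.sufficiency,
                    "prior": result.prior,
                }
            )
    else:
        raise ValueError(f"unknown model {model!r}; expected 'cesm' or 'nsm'")
    return rows


def prediction_table(
    spec: ExperimentSpec,
    model: str,
    s: float,
    w: float = 0.0,
    gamma: Optional[float] = None,
    rounds: Optional[Sequence[str]] = None,
    off_candidate_mode: str = FIXED_AT_ACTUAL,
) -> pd.DataFrame:
    """Exact model scores for every question of the experiment.

    One row per (round, cause).  ``w`` only affects losing rounds.  If
    ``gamma`` is given, a ``scaled`` column with ``max(score, 0)**gamma`` is
    added (the response-scale transform used when fitting).
    """
    wanted = set(rounds) if rounds is not None else None
    all_rows = []
    for rnd in spec.rounds:
        if wanted is not None and rnd.label not in wanted:
            continue
        for row in _score_round(
            spec.scenario, rnd, model, s, w, off_candidate_mode
        ):
            row.update(
                {
                    "experiment": spec.name,
                    "round": rnd.label,
                    "model": model,
                    "s": s,
                    "interpretation_weight": w,
                }
            )
            all_rows.append(row)
    frame = pd.DataFrame(all_rows)
    if gamma is not None:
        from .fitting import scale_prediction

        frame["gamma"] = gamma
        frame["scaled"] = scale_prediction(frame["score"].to_numpy(), gamma)
    leading = ["experiment", "round", "cause", "model", "s",
               "interpretation_weight", "score"]
    other = [c for c in frame.columns if c not in leading]
    return frame[leading + other]


@dataclass
class _LossRoundCache:
    """Per-w scoring contexts for a losing round, sharing the parsed rules."""

    rnd: Round
    base: CausalScenario
    template: CausalScenario
    template_actual: World
    interp: str
    by_w: dict = field(default_factory=dict)

    def context(self, w: float) -> Tuple[CausalScenario, World]:
        if w not in self.by_w:
            scenario = self.template.with_priors({self.interp: w})
            self.by_w[w] = (scenario, scenario.world(
                self.template_actual.assignment))
        return self.by_w[w]


def build_predictor(
    spec: ExperimentSpec,
    model: str,
    rounds: Optional[Sequence[str]] = None,
    off_candidate_mode: str = FIXED_AT_ACTUAL,
) -> Tuple[List[Tuple[str, CandidateCause]], Callable[[float, float], np.ndarray]]:
    """Questions plus a memoized raw-score function ``predict(s, w)``.

    The returned callable computes the exact model score for every question
    (in the returned order) at stability ``s`` and loss-interpretation
    weight ``w``, caching results per parameter pair — grid search and
    repeated fits on the same experiment then reuse each grid point's
    predictions.
    """
    from .loss import INTERPRETATION_VARIABLE

    wanted = set(rounds) if rounds is not None else None
    selected = [
        rnd for rnd in spec.rounds
        if wanted is None or rnd.label in wanted
    ]
    if not selected:
        raise ScenarioError("no rounds selected")
    questions = [
        (rnd.label, cause) for rnd in selected for cause in rnd.questions
    ]
    caches = {}
    for rnd in selected:
        if rnd.polarity == "loss":
            template, template_actual = augment_with_interpretation(
                spec.scenario, rnd.actual, LossInterpretationConfig(0.5)
            )
            caches[rnd.label] = _LossRoundCache(
                rnd, spec.scenario, template, template_actual,
                INTERPRETATION_VARIABLE,
            )

    memo = {}

    def predict(s: float, w: float = 0.0) -> np.ndarray:
        key = (float(s), float(w))
        if key in memo:
            return memo[key]
        config = SamplerConfig(s=float(s))
        scores = []
        for rnd in selected:
            if rnd.polarity == "win":
                scenario, actual = spec.scenario, rnd.actual
            else:
                scenario, actual = caches[rnd.label].context(float(w))
            if model == "cesm":
                dist = enumerate_distribution(scenario, actual, config)
                for cause in rnd.questions:
                    scores.append(
                        cesm_score(
                            scenario, actual, cause, config, distribution=dist
                        ).score
                    )
            elif model == "nsm":
                for cause in rnd.questions:
                    scores.append(
                        nsm_score(
                            scenario, actual, cause, config,
                            off_candidate_mode=off_candidate_mode,
                        ).combined
                    )
            else:
                raise ValueError(f"unknown model {model!r}")
        result = np.asarray(scores, dtype=float)
        memo[key] = result
        return result

    return questions, predict
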