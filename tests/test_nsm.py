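"""Necessity/sufficiency scores and their prior-weighted combination."""

import itertools

import pytest

from pluralcause import CandidateCause, SamplerConfig, necessity, nsm_score, sufficiency
from pluralcause.nsm import (
    FIXED_AT_ACTUAL,
    RESAMPLED,
    necessity_components,
    sufficiency_components,
)
from pluralcause.scenario import (
    CausalScenario,
    ScenarioError,
    VariableSpec,
    parse_rule,
)

import _oracle

DESSERT_PRIORS = {"G": 0.5, "C": 0.8, "B": 0.1}
DESSERT_RULE = lambda w: int(w["G"] + w["C"] + w["B"] >= 2)


class TestDessertWorkedExample:
    """The three-dessert example at s=0: every printed quantity."""

    def test_necessity_of_cake_and_pie(self, dessert, cake_and_pie):
        scenario, actual = dessert
        nec, mass = necessity_components(
            scenario, actual, cake_and_pie, SamplerConfig(s=0.0)
        )
        assert nec == pytest.approx(0.18 / 0.92, abs=1e-12)
        assert mass == pytest.approx(0.92, abs=1e-12)

    def test_sufficiency_of_cake_and_pie(self, dessert, cake_and_pie):
        scenario, actual = dessert
        suf, mass = sufficiency_components(
            scenario, actual, cake_and_pie, SamplerConfig(s=0.0)
        )
        assert suf == pytest.approx(1.0, abs=1e-12)
        assert mass == pytest.approx(0.55, abs=1e-12)

    def test_combined_score(self, dessert, cake_and_pie):
        scenario, actual = dessert
        score = nsm_score(scenario, actual, cake_and_pie, SamplerConfig(s=0.0))
        assert score.prior == pytest.approx(0.08)
        assert score.combined == pytest.approx(0.26, abs=1e-12)


class TestNecessity:
    def test_overdetermined_positive_same_disjunct_pair_is_zero(self, exp2):
        """Negating A&B cannot flip the win while C&D still holds."""
        rnd = exp2.round("overdetermined_positive")
        for s in (0.0, 0.3, 0.7, 0.99):
            assert necessity(
                exp2.scenario, rnd.actual, CandidateCause({"A": 1, "B": 1}),
                SamplerConfig(s=s),
            ) == 0.0

    def test_exp1_singular_low_is_zero(self, exp1):
        """Two remaining colored balls still clear the threshold."""
        rnd = exp1.rounds[0]
        assert necessity(
            exp1.scenario, rnd.actual, CandidateCause({"low": 1}),
            SamplerConfig(s=0.4),
        ) == 0.0

    def test_singleton_necessity_is_deterministic_in_fixed_mode(self, exp1, exp2):
        """Flipping one variable with the rest pinned either flips or not."""
        for spec in (exp1, exp2):
            for rnd in spec.rounds:
                if rnd.polarity != "win":
                    continue
                for cause in rnd.questions:
                    if len(cause) != 1:
                        continue
                    value = necessity(
                        spec.scenario, rnd.actual, cause, SamplerConfig(s=0.37)
                    )
                    assert value in (0.0, 1.0)

    def test_cause_must_hold_in_actual(self, dessert):
        scenario, _ = dessert
        actual = scenario.world({"G": 1, "C": 1, "B": 0})
        with pytest.raises(ScenarioError, match="does not hold"):
            necessity(
                scenario, actual, CandidateCause({"B": 1}), SamplerConfig(s=0.0)
            )

    def test_zero_mass_complement_returns_zero(self, dessert, cake_and_pie):
        scenario, actual = dessert
        assert necessity(
            scenario, actual, cake_and_pie, SamplerConfig(s=1.0)
        ) == 0.0

    def test_resampled_mode_matches_oracle(self, dessert, cake_and_pie):
        scenario, actual = dessert
        for s in (0.0, 0.4):
            expected = _oracle.necessity(
                list(DESSERT_PRIORS), DESSERT_PRIORS, actual.assignment, s,
                {"C": 1, "B": 1}, DESSERT_RULE, mode="resampled",
            )
            got = necessity(
                scenario, actual, cake_and_pie, SamplerConfig(s=s),
                off_candidate_mode=RESAMPLED,
            )
            assert got == pytest.approx(expected, abs=1e-12)


class TestSufficiency:
    def test_conjunction_forcing_the_rule(self):
        scenario = CausalScenario(
            (VariableSpec("A", 0.5), VariableSpec("B", 0.5)),
            parse_rule("A&B", ["A", "B"]),
        )
        actual = scenario.world({"A": 1, "B": 1})
        assert sufficiency(
            scenario, actual, CandidateCause({"A": 1, "B": 1}),
            SamplerConfig(s=0.0),
        ) == pytest.approx(1.0)

    def test_crossing_pair_matches_oracle_and_is_high(self, exp2):
        """Forcing A=1 and C=1 almost always wins (D is usually present)."""
        rnd = exp2.round("overdetermined_positive")
        priors = {"A": 0.7, "B": 0.1, "C": 0.2, "D": 0.9}
        rule = lambda w: int((w["A"] and w["B"]) or (w["C"] and w["D"]))
        expected = _oracle.sufficiency(
            list(priors), priors, rnd.actual.assignment, 0.0,
            {"A": 1, "C": 1}, rule,
        )
        got = sufficiency(
            exp2.scenario, rnd.actual, CandidateCause({"A": 1, "C": 1}),
            SamplerConfig(s=0.0),
        )
        assert got == pytest.approx(expected, abs=1e-12)
        assert got > 0.85


class TestCombined:
    def test_prior_weight_collapse(self, dessert):
        scenario, actual = dessert
        config = SamplerConfig(s=0.0)
        degenerate = CausalScenario(
            (VariableSpec("G", 0.5), VariableSpec("C", 0.0), VariableSpec("B", 1.0)),
            scenario.rule,
        )
        # prior 0 -> combined equals necessity; prior 1 -> equals sufficiency
        world = degenerate.world({"G": 1, "C": 1, "B": 1})
        zero_prior = nsm_score(
            degenerate, world, CandidateCause({"C": 1}), config
        )
        assert zero_prior.prior == 0.0
        assert zero_prior.combined == pytest.approx(zero_prior.necessity)
        one_prior = nsm_score(
            degenerate, world, CandidateCause({"B": 1}), config
        )
        assert one_prior.prior == 1.0
        assert one_prior.combined == pytest.approx(one_prior.sufficiency)

    def test_combined_is_convex_combination_in_unit_interval(self, exp2):
        for rnd in exp2.rounds:
            if rnd.polarity != "win":
                continue
            for cause, s in itertools.product(rnd.questions, (0.0, 0.5)):
                score = nsm_score(
                    exp2.scenario, rnd.actual, cause, SamplerConfig(s=s)
                )
                assert 0.0 <= score.necessity <= 1.0
                assert 0.0 <= score.sufficiency <= 1.0
                lo = min(score.necessity, score.sufficiency) - 1e-12
                hi = max(score.necessity, score.sufficiency) + 1e-12
                assert lo <= score.combined <= hi

    def test_combined_matches_oracle_fixed_mode(self, exp2):
        priors = {"A": 0.7, "B": 0.1, "C": 0.2, "D": 0.9}
        rule = lambda w: int((w["A"] and w["B"]) or (w["C"] and w["D"]))
        rnd = exp2.round("triple_positive")
        for s in (0.0, 0.3, 0.7):
            for cause in rnd.questions:
                expected = _oracle.nsm(
                    list(priors), priors, rnd.actual.assignment, s,
                    cause.as_dict, rule, mode="fixed_at_actual",
                )
                got = nsm_score(
                    exp2.scenario, rnd.actual, cause, SamplerConfig(s=s),
                    off_candidate_mode=FIXED_AT_ACTUAL,
                ).combined
                assert got == pytest.approx(expected, abs=1e-12), (s, cause.label)
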