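import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pluralcause import (
    CandidateCause,
    CausalScenario,
    VariableSpec,
    experiment1,
    experiment2,
    parse_rule,
)


@pytest.fixture(scope="session")
def dessert():
    """The three-dessert scenario: stomachache iff two or more eaten."""
    variables = (
        VariableSpec("G", 0.5),
        VariableSpec("C", 0.8),
        VariableSpec("B", 0.1),
    )
    rule = parse_rule("count(G,C,B)>=2", ["G", "C", "B"])
    scenario = CausalScenario(variables, rule, label="dessert")
    actual = scenario.world({"G": 1, "C": 1, "B": 1})
    return scenario, actual


@pytest.fixture(scope="session")
def cake_and_pie():
    return CandidateCause({"C": 1, "B": 1})


@pytest.fixture(scope="session")
def exp1():
    return experiment1()


@pytest.fixture(scope="session")
def exp2():
    return experiment2()
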