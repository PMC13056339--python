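"""Causal scenarios with binary exogenous variables and a Boolean outcome rule.

A scenario is the generative frame for all causal-strength scoring: a set of
named binary variables, each with an independent prior probability (its
"normality" — how expected the event is), and a Boolean rule mapping a
complete assignment of the variables to a binary outcome.  Candidate causes
are conjunctions of literals over those variables; a singular cause is the
special case with one literal, a plural (conjunctive) cause has several.

The rule grammar supports ``&`` (and), ``|`` (or), ``!`` (not), parentheses
and the threshold form ``count(v1,...,vk)>=m``, with precedence
``!`` > ``&`` > ``|``.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "RuleSyntaxError",
    "ScenarioError",
    "VariableSpec",
    "OutcomeRule",
    "CausalScenario",
    "World",
    "CandidateCause",
    "parse_rule",
    "evaluate_outcome",
    "cause_indicator",
    "cause_prior",
    "world_matrix",
]


class ScenarioError(ValueError):
    """Invalid scenario, world, or candidate-cause construction."""


class RuleSyntaxError(ScenarioError):
    """Malformed rule expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# Rule AST
# ---------------------------------------------------------------------------

class _Node:
    def eval(self, env):  # pragma: no cover - abstract
        raise NotImplementedError

    def names(self) -> set:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class _Var(_Node):
    name: str

    def eval(self, env):
        return env[self.name]

    def names(self):
        return {self.name}


@dataclass(frozen=True)
class _Not(_Node):
    child: _Node

    def eval(self, env):
        return 1 - self.child.eval(env)

    def names(self):
        return self.child.names()


@dataclass(frozen=True)
class _And(_Node):
    left: _Node
    right: _Node

    def eval(self, env):
        return self.left.eval(env) * self.right.eval(env)

    def names(self):
        return self.left.names() | self.right.names()


@dataclass(frozen=True)
class _Or(_Node):
    left: _Node
    right: _Node

    def eval(self, env):
        a = self.left.eval(env)
        b = self.right.eval(env)
        return a + b - a * b

    def names(self):
        return self.left.names() | self.right.names()


@dataclass(frozen=True)
class _Count(_Node):
    members: tuple
    threshold: int

    def eval(self, env):
        total = sum(env[name] for name in self.members)
        if isinstance(total, np.ndarray):
            return (total >= self.threshold).astype(np.uint8)
        return int(total >= self.threshold)

    def names(self):
        return set(self.members)


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<int>\d+)|(?P<ge>>=)"
    r"|(?P<sym>[&|!(),]))"
)


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            at = len(text) - len(stripped)
            raise RuleSyntaxError(f"unexpected character {stripped[0]!r}", at)
        if m.lastgroup == "ident":
            tokens.append(("ident", m.group("ident"), m.start("ident")))
        elif m.lastgroup == "int":
            tokens.append(("int", int(m.group("int")), m.start("int")))
        elif m.lastgroup == "ge":
            tokens.append((">=", ">=", m.start("ge")))
        else:
            sym = m.group("sym")
            tokens.append((sym, sym, m.start("sym")))
        pos = m.end()
    tokens.append(("end", None, len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser for the rule grammar (``!`` > ``&`` > ``|``)."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str):
        tok = self.advance()
        if tok[0] != kind:
            raise RuleSyntaxError(f"expected {kind!r}, found {tok[1]!r}", tok[2])
        return tok

    def parse(self) -> _Node:
        node = self.parse_or()
        tok = self.peek()
        if tok[0] != "end":
            raise RuleSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def parse_or(self) -> _Node:
        node = self.parse_and()
        while self.peek()[0] == "|":
            self.advance()
            node = _Or(node, self.parse_and())
        return node

    def parse_and(self) -> _Node:
        node = self.parse_not()
        while self.peek()[0] == "&":
            self.advance()
            node = _And(node, self.parse_not())
        return node

    def parse_not(self) -> _Node:
        if self.peek()[0] == "!":
            self.advance()
            return _Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> _Node:
        tok = self.advance()
        if tok[0] == "(":
            node = self.parse_or()
            self.expect(")")
            return node
        if tok[0] == "ident":
            if tok[1] == "count" and self.peek()[0] == "(":
                return self.parse_count()
            return _Var(tok[1])
        raise RuleSyntaxError(f"expected a variable or '(', found {tok[1]!r}", tok[2])

    def parse_count(self) -> _Node:
        self.expect("(")
        members = [self.expect("ident")[1]]
        while self.peek()[0] == ",":
            self.advance()
            members.append(self.expect("ident")[1])
        self.expect(")")
        self.expect(">=")
        threshold = self.expect("int")[1]
        return _Count(tuple(members), threshold)


@dataclass(frozen=True)
class OutcomeRule:
    """A Boolean formula over variable names, evaluable on any total world.

    Evaluation is vector-aware: assignment values may be scalars in ``{0, 1}``
    or equal-length numpy 0/1 arrays, in which case the result is an array.
    """

    expression: str
    _ast: _Node = field(repr=False, compare=False)

    @property
    def variables(self) -> frozenset:
        return frozenset(self._ast.names())

    def evaluate(self, assignment: Mapping[str, int]):
        missing = self.variables - set(assignment)
        if missing:
            raise ScenarioError(
                f"assignment is missing variables: {sorted(missing)}"
            )
        value = self._ast.eval(assignment)
        if isinstance(value, np.ndarray):
            return value.astype(np.uint8)
        return int(value)

    __call__ = evaluate


def parse_rule(text: str, variables: Iterable[str]) -> OutcomeRule:
    """Parse a rule expression and check it only references known variables.

    Parameters
    ----------
    text:
        Expression in the grammar ``ident``, ``&``, ``|``, ``!``, parentheses,
        ``count(v1,...,vk)>=m``; whitespace is insignificant.
    variables:
        Names declared by the scenario.

    Raises
    ------
    RuleSyntaxError
        On malformed syntax, with the character position.
    ScenarioError
        If the expression references an undeclared variable.
    """
    ast = _Parser(text).parse()
    known = set(variables)
    unknown = ast.names() - known
    if unknown:
        raise ScenarioError(
            f"rule references unknown variable(s): {sorted(unknown)}"
        )
    return OutcomeRule(expression=text, _ast=ast)


# ---------------------------------------------------------------------------
# Scenario, world, cause
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """A binary exogenous variable.

    ``prior`` is the marginal probability that the variable takes value 1.
    ``anchored`` marks whether counterfactual sampling may keep the variable
    at its actual value (the normal case); unanchored variables are always
    resampled fresh from their prior, which is how the loss-interpretation
    mixture variable is represented.
    """

    name: str
    prior: float
    anchored: bool = True

    def __post_init__(self):
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", self.name):
            raise ScenarioError(f"invalid variable name {self.name!r}")
        if not 0.0 <= self.prior <= 1.0:
            raise ScenarioError(
                f"prior for {self.name!r} must lie in [0, 1], got {self.prior}"
            )


@functools.lru_cache(maxsize=32)
def world_matrix(n: int) -> np.ndarray:
    """All ``2**n`` binary assignments as a ``(2**n, n)`` 0/1 array.

    Row ``i`` spells the binary expansion of ``i``, most significant bit in
    column 0, so that row order is the natural integer order.
    """
    idx = np.arange(2**n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1)
    return ((idx[:, None] >> shifts) & 1).astype(np.uint8)


@dataclass
class CausalScenario:
    """Named binary variables with priors plus the outcome rule."""

    variables: tuple
    rule: OutcomeRule
    label: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.variables = tuple(self.variables)
        if not self.variables:
            raise ScenarioError("a scenario needs at least one variable")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ScenarioError("variable names must be unique")
        undeclared = self.rule.variables - set(names)
        if undeclared:
            raise ScenarioError(
                f"rule references undeclared variable(s): {sorted(undeclared)}"
            )

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> tuple:
        return tuple(v.name for v in self.variables)

    @property
    def priors(self) -> np.ndarray:
        return np.array([v.prior for v in self.variables], dtype=float)

    @property
    def anchored_mask(self) -> np.ndarray:
        return np.array([v.anchored for v in self.variables], dtype=bool)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ScenarioError(f"unknown variable {name!r}") from None

    def outcome_vector(self) -> np.ndarray:
        """Rule value over all ``2**n`` worlds (cached; column order = ``names``)."""
        if "outcomes" not in self._cache:
            worlds = world_matrix(self.n)
            env = {name: worlds[:, j] for j, name in enumerate(self.names)}
            self._cache["outcomes"] = self.rule.evaluate(env)
        return self._cache["outcomes"]

    def with_priors(self, updates: Mapping[str, float]) -> "CausalScenario":
        """A copy with some priors replaced; shares the rule and outcome cache."""
        new_vars = []
        for v in self.variables:
            if v.name in updates:
                new_vars.append(
                    VariableSpec(v.name, float(updates[v.name]), v.anchored)
                )
            else:
                new_vars.append(v)
        clone = CausalScenario(tuple(new_vars), self.rule, self.label)
        clone._cache = self._cache  # outcomes depend only on the rule
        return clone

    def world(self, assignment: Mapping[str, int]) -> "World":
        """Build a :class:`World`, deriving the outcome from the rule."""
        missing = set(self.names) - set(assignment)
        if missing:
            raise ScenarioError(f"assignment is missing: {sorted(missing)}")
        values = {}
        for name in self.names:
            value = int(assignment[name])
            if value not in (0, 1):
                raise ScenarioError(
                    f"value for {name!r} must be 0 or 1, got {assignment[name]}"
                )
            values[name] = value
        return World(assignment=values, outcome=self.rule.evaluate(values))

    @classmethod
    def from_config(cls, config: Mapping) -> "CausalScenario":
        """Build from a config mapping with keys ``variables``, ``rule``, ``label``."""
        specs = tuple(
            VariableSpec(entry["name"], float(entry["prior"]))
            for entry in config["variables"]
        )
        rule = parse_rule(config["rule"], [v.name for v in specs])
        return cls(specs, rule, label=config.get("label", ""))


@dataclass(frozen=True)
class World:
    """A complete 0/1 assignment with its derived outcome."""

    assignment: Mapping[str, int]
    outcome: int

    def __post_init__(self):
        object.__setattr__(self, "assignment", dict(self.assignment))

    def __getitem__(self, name: str) -> int:
        return self.assignment[name]

    def values_for(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.assignment[n] for n in names], dtype=np.uint8)


@dataclass(frozen=True)
class CandidateCause:
    """A non-empty conjunction of literals (variable, required value).

    Represents singular and plural causes alike; a required value of 0 is a
    negative event ("drew a white ball").  The canonical string form sorts
    literals by name, prefixes required-0 literals with ``!`` and joins with
    ``&``, e.g. ``"!A&!D"``.
    """

    literals: tuple  # sorted tuple of (name, value)

    def __init__(self, literals: Mapping[str, int]):
        items = dict(literals)
        if not items:
            raise ScenarioError("a candidate cause needs at least one literal")
        norm = []
        for name, value in items.items():
            value = int(value)
            if value not in (0, 1):
                raise ScenarioError(
                    f"literal value for {name!r} must be 0 or 1, got {value}"
                )
            norm.append((name, value))
        object.__setattr__(self, "literals", tuple(sorted(norm)))

    @classmethod
    def from_string(cls, text: str) -> "CandidateCause":
        """Parse the ``&``/``!`` serialization, e.g. ``"!A&B"``."""
        items = {}
        for part in text.split("&"):
            part = part.strip()
            if not part:
                raise ScenarioError(f"empty literal in cause string {text!r}")
            value = 1
            if part.startswith("!"):
                value = 0
                part = part[1:].strip()
            if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", part):
                raise ScenarioError(f"invalid literal {part!r} in cause {text!r}")
            if part in items:
                raise ScenarioError(f"variable {part!r} repeated in cause {text!r}")
            items[part] = value
        return cls(items)

    @property
    def as_dict(self) -> dict:
        return dict(self.literals)

    @property
    def names(self) -> tuple:
        return tuple(name for name, _ in self.literals)

    @property
    def label(self) -> str:
        return "&".join(
            ("" if value else "!") + name for name, value in self.literals
        )

    def __len__(self) -> int:
        return len(self.literals)

    def validate(self, scenario: CausalScenario) -> None:
        for name in self.names:
            scenario.index(name)

    def holds_in(self, assignment: Mapping[str, int]) -> bool:
        return all(assignment[name] == value for name, value in self.literals)

    def indicator(self, worlds: np.ndarray, names: Iterable[str]) -> np.ndarray:
        """Vectorized indicator over a ``(m, n)`` world matrix."""
        names = list(names)
        out = np.ones(worlds.shape[0], dtype=np.uint8)
        for name, value in self.literals:
            out &= (worlds[:, names.index(name)] == value).astype(np.uint8)
        return out

    def __str__(self) -> str:
        return self.label


def evaluate_outcome(scenario: CausalScenario, assignment: Mapping[str, int]) -> int:
    """Rule value on a total assignment (pure function)."""
    return scenario.world(assignment).outcome


def cause_indicator(cause: CandidateCause, world: World) -> int:
    """1 iff every literal of ``cause`` is satisfied in ``world``."""
    return int(cause.holds_in(world.assignment))


def cause_prior(cause: CandidateCause, scenario: CausalScenario) -> float:
    """Prior probability of the cause: product over literals of P(V=v).

    For a plural this is always at most the smallest constituent literal
    prior, which is what tilts the necessity/sufficiency weighting of plural
    causes toward necessity.
    """
    cause.validate(scenario)
    prob = 1.0
    for name, value in cause.literals:
        p = scenario.variables[scenario.index(name)].prior
        prob *= p if value == 1 else 1.0 - p
    return prob
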