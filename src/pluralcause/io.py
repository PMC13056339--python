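"""Readers and writers for the package's file formats.

Scenario configs are YAML or JSON mappings with keys ``variables`` (list of
``{name, prior}``), ``rule`` (string in the rule grammar), optional
``actual`` (map name -> 0/1) and ``label``.  Ratings travel as CSV with
columns ``participant_id, experiment, round, cause, rating``; causes use
the canonical ``&``/``!`` serialization.  Fit reports are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd
import yaml

from .fitting import FitResult
from .scenario import CandidateCause, CausalScenario, ScenarioError, World

RATING_COLUMNS = ["participant_id", "experiment", "round", "cause", "rating"]


def read_scenario(path) -> Tuple[CausalScenario, Optional[World]]:
    """Load a scenario config (and its actual world, if given)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ScenarioError(f"scenario config {path} is not a mapping")
    scenario = CausalScenario.from_config(config)
    actual = None
    if "actual" in config:
        actual = scenario.world(config["actual"])
    return scenario, actual


def write_scenario(scenario: CausalScenario, path, actual: Optional[World] = None):
    config = {
        "label": scenario.label,
        "variables": [
            {"name": v.name, "prior": v.prior} for v in scenario.variables
        ],
        "rule": scenario.rule.expression,
    }
    if actual is not None:
        config["actual"] = dict(actual.assignment)
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_ratings(path, known_variables=None) -> pd.DataFrame:
    """Read and validate a ratings CSV.

    Checks the header, integer ratings in [1, 9], parseable cause strings
    and (optionally) that every cause variable is known.  Errors name the
    offending row.
    """
    frame = pd.read_csv(path)
    missing = set(RATING_COLUMNS) - set(frame.columns)
    if missing:
        raise ScenarioError(
            f"ratings file {path} is missing columns: {sorted(missing)}"
        )
    if frame.empty:
        raise ScenarioError(f"ratings file {path} has no data rows")
    known = set(known_variables) if known_variables is not None else None
    for idx, row in frame.iterrows():
        rating = row["rating"]
        if not float(rating).is_integer() or not 1 <= int(rating) <= 9:
            raise ScenarioError(
                f"row {idx}: rating {rating!r} is not an integer in [1, 9]"
            )
        cause = CandidateCause.from_string(str(row["cause"]))
        if known is not None:
            unknown = set(cause.names) - known
            if unknown:
                raise ScenarioError(
                    f"row {idx}: unknown variable(s) {sorted(unknown)} in "
                    f"cause {row['cause']!r}"
                )
    frame["rating"] = frame["rating"].astype(int)
    # Canonicalize cause serialization so joins against predictions work.
    frame["cause"] = [
        CandidateCause.from_string(str(c)).label for c in frame["cause"]
    ]
    return frame


def write_ratings(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=RATING_COLUMNS)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable run configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_fit_report(fit: FitResult, path, extra: Optional[dict] = None) -> None:
    report = fit.to_dict()
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
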