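"""Simulated Likert-rating datasets with the structure the fitting assumes.

Each simulated participant rates every question of an experiment.  The
latent response for participant i on question q is

    scale_prediction(model_score_q, gamma) + intercept_i + noise_iq,

with a mean-zero normal participant intercept (response style / anchoring
variance, shared across that participant's questions) and independent
mean-zero normal noise per rating.  The latent value maps onto the 1-9
agreement scale via r = 1 + 8*latent, then rounds and clips to {1..9}.

Defaults: noise_sd = 0.25 and intercept_sd = 0.15 in latent (rescaled [0,1])
units, i.e. per-rating noise of about two Likert points and a participant
spread of about one point — typical for single-item 1-9 agreement scales.
The generator reproduces the mean structure and participant-level variance
of real rating data but none of its ordinal skew, order-of-presentation
effects, or per-participant parameter heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .experiments import ExperimentSpec, build_predictor
from .fitting import FitConfig, FitResult, grid_fit, scale_prediction

__all__ = [
    "RatingDataset",
    "RecoveryReport",
    "generate_ratings",
    "recovery_study",
]

DEFAULT_NOISE_SD = 0.25
DEFAULT_INTERCEPT_SD = 0.15


@dataclass
class RatingDataset:
    """Long-format ratings plus the generating configuration."""

    frame: pd.DataFrame  # participant_id, experiment, round, cause, rating
    metadata: dict

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class RecoveryReport:
    """Per-replication estimates and the median absolute errors."""

    estimates: pd.DataFrame
    true_params: dict
    median_abs_error: Dict[str, float]


def generate_ratings(
    spec: ExperimentSpec,
    model: str,
    true_params: dict,
    n_participants: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    intercept_sd: float = DEFAULT_INTERCEPT_SD,
    seed: Optional[int] = None,
    rounds: Optional[Sequence[str]] = None,
    predictor=None,
) -> RatingDataset:
    """Simulate integer 1-9 ratings for every (participant, question).

    ``true_params`` holds ``s``, ``gamma`` and (for losing rounds) ``w``.
    A prebuilt ``(questions, predict)`` pair from :func:`build_predictor`
    may be passed to amortize prediction work across replications.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if noise_sd < 0 or intercept_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if seed is None:
        raise ValueError("a seed is required")
    questions, predict = (
        build_predictor(spec, model, rounds=rounds)
        if predictor is None
        else predictor
    )
    s = float(true_params["s"])
    w = float(true_params.get("w", 0.0))
    gamma = float(true_params.get("gamma", 1.0))
    scaled = scale_prediction(predict(s, w), gamma)

    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, intercept_sd, size=n_participants)
    noise = rng.normal(0.0, noise_sd, size=(n_participants, len(questions)))
    latent = scaled[None, :] + intercepts[:, None] + noise
    ratings = np.clip(np.rint(1.0 + 8.0 * latent), 1, 9).astype(int)

    rows = {
        "participant_id": np.repeat(
            [f"p{i + 1}" for i in range(n_participants)], len(questions)
        ),
        "experiment": spec.name,
        "round": np.tile([label for label, _ in questions], n_participants),
        "cause": np.tile([cause.label for _, cause in questions], n_participants),
        "rating": ratings.ravel(),
    }
    frame = pd.DataFrame(rows)
    metadata = {
        "experiment": spec.name,
        "model": model,
        "true_params": {"s": s, "w": w, "gamma": gamma},
        "noise_sd": noise_sd,
        "intercept_sd": intercept_sd,
        "n_participants": n_participants,
        "seed": seed,
        "rounds": list(rounds) if rounds is not None else None,
    }
    return RatingDataset(frame=frame, metadata=metadata)


def recovery_study(
    spec: ExperimentSpec,
    model: str,
    true_params: dict,
    n_participants: int,
    reps: int,
    seed: int,
    fit_config: Optional[FitConfig] = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    intercept_sd: float = DEFAULT_INTERCEPT_SD,
    rounds: Optional[Sequence[str]] = None,
) -> RecoveryReport:
    """Repeatedly simulate, fit, and summarize parameter recovery.

    Each replication draws a fresh dataset from the generating model,
    collapses it to question means, and refits by grid search.  Model
    predictions are memoized across replications (they do not depend on the
    data), so the per-replication cost is the likelihood sweep only.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    questions, predict = build_predictor(spec, model, rounds=rounds)
    if fit_config is None:
        from .fitting import default_w_grid

        fit_config = FitConfig(
            w_grid=default_w_grid() if "w" in true_params else None
        )
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    for rep, child in enumerate(child_seeds):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        data = generate_ratings(
            spec,
            model,
            true_params,
            n_participants,
            noise_sd=noise_sd,
            intercept_sd=intercept_sd,
            seed=rep_seed,
            rounds=rounds,
            predictor=(questions, predict),
        )
        # Means in the generator's question order.
        means = (
            data.frame.groupby(["round", "cause"], sort=False)["rating"]
            .mean()
            .to_numpy()
        )
        fit = grid_fit(predict, means, fit_config, model=model)
        rows.append(
            {
                "rep": rep,
                "seed": rep_seed,
                "s": fit.s,
                "w": fit.w,
                "gamma": fit.gamma,
                "loglik": fit.loglik,
            }
        )
    estimates = pd.DataFrame(rows)
    median_abs_error = {}
    for name in ("s", "w", "gamma"):
        if name in true_params and estimates[name].notna().all():
            median_abs_error[name] = float(
                (estimates[name] - float(true_params[name])).abs().median()
            )
    return RecoveryReport(
        estimates=estimates,
        true_params=dict(true_params),
        median_abs_error=median_abs_error,
    )
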