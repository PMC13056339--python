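"""Grid-search maximum-likelihood fitting of (s, w, gamma) to question means.

Observed mean ratings on the 1-9 agreement scale are affinely rescaled to
[0, 1] via (m - 1)/8 and compared with model scores passed through the
response transform max(score, 0)**gamma (gamma straightens systematic over-
or undershoot without changing the predicted ordering; negative raw scores
are clipped to 0 before exponentiation).  The fit surface is the Gaussian
log-likelihood of the rescaled means around the transformed predictions,
with the residual standard deviation sigma profiled out in closed form (its
maximum-likelihood value, the RMS residual) at each grid point.  The argmax
over the (s[, w], gamma) grid is returned; ties break toward smaller s,
then smaller w, then smaller gamma.

Baselines: a constant model predicting 0.5**gamma for every question
(fitted via gamma only), and the linear-combination null that predicts each
pair's mean rating as the average of its constituent singulars' mean
ratings.  Model comparison uses AIC = 2k - 2*loglik and
BIC = k*ln(Q) - 2*loglik with Q the number of questions and k counting the
fitted parameters including sigma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FitConfig",
    "FitResult",
    "scale_prediction",
    "grid_fit",
    "constant_baseline_fit",
    "linear_combination_baseline",
    "compare_models",
    "question_means",
]

logger = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-9


def default_s_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0001, 0.01), 10)


def default_w_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0001, 0.01), 10)


def default_gamma_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 3.0001, 0.05), 10)


@dataclass
class FitConfig:
    """Finite ascending search grids; ``w_grid=None`` fits positive-only models."""

    s_grid: np.ndarray = field(default_factory=default_s_grid)
    w_grid: Optional[np.ndarray] = None
    gamma_grid: np.ndarray = field(default_factory=default_gamma_grid)

    def __post_init__(self):
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.gamma_grid = np.asarray(self.gamma_grid, dtype=float)
        if self.w_grid is not None:
            self.w_grid = np.asarray(self.w_grid, dtype=float)
        for name, grid in (("s_grid", self.s_grid),
                           ("gamma_grid", self.gamma_grid),
                           ("w_grid", self.w_grid)):
            if grid is None:
                continue
            if grid.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
        if np.any(self.gamma_grid <= 0):
            raise ValueError("gamma values must be positive")
        if np.any((self.s_grid < 0) | (self.s_grid > 1)):
            raise ValueError("s values must lie in [0, 1]")
        if self.w_grid is not None and np.any(
            (self.w_grid < 0) | (self.w_grid > 1)
        ):
            raise ValueError("w values must lie in [0, 1]")


@dataclass(frozen=True)
class FitResult:
    """Best grid point with its likelihood and information criteria."""

    s: Optional[float]
    w: Optional[float]
    gamma: Optional[float]
    sigma: float
    loglik: float
    aic: float
    bic: float
    correlation: float
    n_questions: int
    n_params: int
    model: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "s": self.s,
            "w": self.w,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "correlation": self.correlation,
            "n_questions": self.n_questions,
            "n_params": self.n_params,
        }


def scale_prediction(raw, gamma: float):
    """Response transform ``max(raw, 0)**gamma`` (gamma > 0).

    Correlation-based scores can be slightly negative; exponentiation of a
    negative base is undefined, so they clip to 0 (and the event is logged).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < 0):
        logger.debug("clipping %d negative raw score(s) to 0", int((arr < 0).sum()))
    clipped = np.clip(arr, 0.0, None)
    result = clipped**gamma
    return result if arr.ndim else float(result)


def rescale_means(means) -> np.ndarray:
    """Map 1-9 Likert means onto [0, 1] via (m - 1)/8."""
    return (np.asarray(means, dtype=float) - 1.0) / 8.0


def _gaussian_profile_loglik(y: np.ndarray, preds: np.ndarray) -> Tuple[float, float]:
    """(loglik, sigma) with sigma at its closed-form ML value (RMS residual)."""
    q = y.size
    rss = float(np.sum((y - preds) ** 2))
    sigma = max(math.sqrt(rss / q), _SIGMA_FLOOR)
    loglik = -0.5 * q * math.log(2.0 * math.pi * sigma**2) - rss / (2.0 * sigma**2)
    return loglik, sigma


def _safe_correlation(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def grid_fit(
    predict: Callable[[float, float], np.ndarray],
    means: Sequence[float],
    config: Optional[FitConfig] = None,
    model: str = "",
) -> FitResult:
    """Exhaustive grid search of the profiled Gaussian likelihood.

    Parameters
    ----------
    predict:
        Callable mapping ``(s, w)`` to the raw model scores for the fitted
        questions, in the same order as ``means``.  ``w`` is passed as 0.0
        when ``config.w_grid`` is None.
    means:
        Observed per-question mean ratings on the 1-9 scale.
    config:
        Search grids; defaults to the standard dense grids.
    """
    config = config or FitConfig()
    y = rescale_means(means)
    if y.size == 0:
        raise ValueError("no question means to fit")
    gammas = config.gamma_grid
    w_values: Iterable[Optional[float]] = (
        [None] if config.w_grid is None else config.w_grid
    )

    best = None  # (loglik, s, w, gamma, sigma, preds)
    for s in config.s_grid:
        for w in w_values:
            raw = np.asarray(
                predict(float(s), 0.0 if w is None else float(w)), dtype=float
            )
            if raw.shape != y.shape:
                raise ValueError(
                    f"predict returned {raw.shape}, expected {y.shape}"
                )
            if not np.all(np.isfinite(raw)):
                raise ValueError("predict returned non-finite scores")
            clipped = np.clip(raw, 0.0, None)
            preds = clipped[None, :] ** gammas[:, None]
            rss = np.sum((y[None, :] - preds) ** 2, axis=1)
            q = y.size
            sigma = np.maximum(np.sqrt(rss / q), _SIGMA_FLOOR)
            loglik = (
                -0.5 * q * np.log(2.0 * math.pi * sigma**2)
                - rss / (2.0 * sigma**2)
            )
            j = int(np.argmax(loglik))
            # Ascending iteration order + strict improvement implements the
            # tie-break toward smaller s, then w, then gamma.
            if best is None or loglik[j] > best[0] + 0.0:
                best = (
                    float(loglik[j]),
                    float(s),
                    None if w is None else float(w),
                    float(gammas[j]),
                    float(sigma[j]),
                    preds[j],
                )

    loglik, s_hat, w_hat, gamma_hat, sigma_hat, preds = best
    k = 3 + (0 if w_hat is None else 1)  # s, (w), gamma, sigma
    q = y.size
    return FitResult(
        s=s_hat,
        w=w_hat,
        gamma=gamma_hat,
        sigma=sigma_hat,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(q) - 2 * loglik,
        correlation=_safe_correlation(preds, y),
        n_questions=q,
        n_params=k,
        model=model,
    )


def constant_baseline_fit(
    means: Sequence[float],
    gamma_grid: Optional[np.ndarray] = None,
    model: str = "constant",
) -> FitResult:
    """Baseline predicting ``0.5**gamma`` for every question (k = 2).

    The correlation of a constant with anything is undefined and reported
    as 0 by convention.
    """
    y = rescale_means(means)
    if y.size == 0:
        raise ValueError("no question means to fit")
    gammas = np.asarray(
        default_gamma_grid() if gamma_grid is None else gamma_grid, dtype=float
    )
    best = None
    for gamma in gammas:
        preds = np.full_like(y, 0.5**gamma)
        loglik, sigma = _gaussian_profile_loglik(y, preds)
        if best is None or loglik > best[0]:
            best = (loglik, float(gamma), sigma)
    loglik, gamma_hat, sigma_hat = best
    q = y.size
    k = 2  # gamma, sigma
    return FitResult(
        s=None,
        w=None,
        gamma=gamma_hat,
        sigma=sigma_hat,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(q) - 2 * loglik,
        correlation=0.0,
        n_questions=q,
        n_params=k,
        model=model,
    )


def linear_combination_baseline(
    singular_means: Dict[str, float],
    pairs: Sequence[Tuple[str, str]],
) -> List[float]:
    """Pair predictions as the average of the constituent singular means.

    Operates on the raw 1-9 scale (rescale afterwards for likelihoods).
    """
    predictions = []
    for a, b in pairs:
        for name in (a, b):
            if name not in singular_means:
                raise KeyError(f"missing singular mean for {name!r}")
        predictions.append(0.5 * (singular_means[a] + singular_means[b]))
    return predictions


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Comparison table of log-likelihood, AIC, BIC and correlation."""
    if not fits:
        raise ValueError("no fits to compare")
    q = {fit.n_questions for fit in fits}
    if len(q) != 1:
        raise ValueError(
            "fits were computed on different question sets; refusing to compare"
        )
    rows = [fit.to_dict() for fit in fits]
    return pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)


def question_means(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-(round, cause) mean rating and respondent count, in rating-file order."""
    required = {"round", "cause", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings frame is missing columns: {sorted(missing)}")
    grouped = (
        ratings.groupby(["round", "cause"], sort=False)["rating"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    return grouped
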