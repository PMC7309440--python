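"""Discrimination and calibration statistics.

The central statistic is the concordance (C) index for a continuous or
ordinal outcome: the proportion of usable subject pairs (pairs with unequal
outcomes) in which predictions and outcomes are ordered the same way; tied
predictions on a usable pair receive half credit.  Confidence intervals come
from the nonparametric (percentile) bootstrap on the pooled cohort, with
paired resampling when two models are compared on the same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression


class DegenerateMetricError(ValueError):
    """The metric is undefined on this input (e.g. all outcomes equal)."""


@dataclass(frozen=True)
class EvalConfig:
    B: int = 1000  # bootstrap replicates
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


def c_index(predictions: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance index in [0, 1].

    Usable pairs are those with unequal outcomes.  A pair is concordant when
    predictions and outcomes are ordered alike; prediction ties contribute
    0.5.  Raises :class:`DegenerateMetricError` when all outcomes are equal.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predictions and outcomes must be 1-D and equal length")
    dy = y[:, None] - y[None, :]
    usable = dy > 0  # orient each usable pair once: i has the larger outcome
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise DegenerateMetricError("all outcomes equal; C index undefined")
    dp = p[:, None] - p[None, :]
    concordant = float((dp[usable] > 0).sum())
    ties = float((dp[usable] == 0).sum())
    return (concordant + 0.5 * ties) / n_usable


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    predictions: np.ndarray,
    outcomes: np.ndarray,
    cfg: EvalConfig = EvalConfig(),
) -> tuple[float, float]:
    """Percentile bootstrap interval for a paired (prediction, outcome) metric.

    Resamples subjects with replacement; replicates on which the metric is
    undefined are skipped (their count is tracked, and more than 50%
    degenerate replicates is an error).  Deterministic given the seed.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    values, skipped = [], 0
    for _ in range(cfg.B):
        idx = rng.integers(0, len(y), size=len(y))
        try:
            values.append(metric(p[idx], y[idx]))
        except DegenerateMetricError:
            skipped += 1
    if skipped > cfg.B / 2:
        raise DegenerateMetricError(
            f"{skipped}/{cfg.B} bootstrap replicates were degenerate"
        )
    lo = 100 * (1 - cfg.ci_level) / 2
    return (
        float(np.percentile(values, lo)),
        float(np.percentile(values, 100 - lo)),
    )


# ---------------------------------------------------------------------------
# Calibration

@dataclass(frozen=True)
class CalibrationModel:
    slope: float
    intercept: float
    lam: float = 0.01  # L1 regularization coefficient

    def apply(self, predictions: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(predictions, dtype=float) + self.intercept


def calibrate(
    train_predictions: np.ndarray, train_outcomes: np.ndarray, lam: float = 0.01
) -> CalibrationModel:
    """Univariate L1-regularised (lasso) linear map from raw model output to
    the outcome, fitted on training predictions.  lam=0 reduces to ordinary
    least squares."""
    p = np.asarray(train_predictions, dtype=float).reshape(-1, 1)
    y = np.asarray(train_outcomes, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 points to calibrate")
    if np.ptp(p) == 0:
        raise DegenerateMetricError("constant predictions cannot be calibrated")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        model = LinearRegression().fit(p, y)
    else:
        model = Lasso(alpha=lam, max_iter=100_000, tol=1e-12).fit(p, y)
    return CalibrationModel(
        slope=float(np.ravel(model.coef_)[0]), intercept=float(model.intercept_), lam=lam
    )


@dataclass(frozen=True)
class FitMetrics:
    r_squared: float
    mean_absolute_error: float
    slope: float
    intercept: float


def fit_metrics(
    calibration: CalibrationModel, predictions: np.ndarray, outcomes: np.ndarray
) -> FitMetrics:
    """Goodness of fit of calibrated predictions: R^2 and mean absolute error."""
    y = np.asarray(outcomes, dtype=float)
    yhat = calibration.apply(predictions)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateMetricError("zero outcome variance; R^2 undefined")
    ss_res = float(((y - yhat) ** 2).sum())
    return FitMetrics(
        r_squared=1.0 - ss_res / ss_tot,
        mean_absolute_error=float(np.abs(y - yhat).mean()),
        slope=calibration.slope,
        intercept=calibration.intercept,
    )


# ---------------------------------------------------------------------------
# Paired model comparison

@dataclass(frozen=True)
class DeltaCResult:
    delta_c: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        """True when the bootstrap CI excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


def delta_c_index(
    preds_a: np.ndarray,
    preds_b: np.ndarray,
    outcomes: np.ndarray,
    cfg: EvalConfig = EvalConfig(),
) -> DeltaCResult:
    """C(A) - C(B) with a paired bootstrap CI: the same resample indices are
    applied to both models so the interval reflects the paired design."""
    a = np.asarray(preds_a, dtype=float)
    b = np.asarray(preds_b, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("prediction vectors and outcomes must be aligned")
    point = c_index(a, y) - c_index(b, y)
    rng = np.random.default_rng(cfg.seed)
    deltas, skipped = [], 0
    for _ in range(cfg.B):
        idx = rng.integers(0, len(y), size=len(y))
        try:
            deltas.append(c_index(a[idx], y[idx]) - c_index(b[idx], y[idx]))
        except DegenerateMetricError:
            skipped += 1
    if skipped > cfg.B / 2:
        raise DegenerateMetricError(f"{skipped}/{cfg.B} paired replicates degenerate")
    lo = 100 * (1 - cfg.ci_level) / 2
    return DeltaCResult(
        delta_c=point,
        ci_low=float(np.percentile(deltas, lo)),
        ci_high=float(np.percentile(deltas, 100 - lo)),
    )
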