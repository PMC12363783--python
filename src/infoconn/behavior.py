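"""Behavioral training and transfer metrics.

Implements the training distance-error normalization, the two transfer
learning rates, day-wise training regression slopes, and the
correlation machinery (normality-gated Pearson/Spearman, partial
correlation via residualization, and Fisher z comparison of two
correlations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError, UndefinedResultError

TRAINING_THRESHOLD_FACTOR = 1.2


@dataclass(frozen=True)
class NavTrial:
    """One navigation trial: shortest possible vs traveled path length."""

    trial_index: int
    shortest_path_length: float
    traveled_length: float
    subsection: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.shortest_path_length) or not np.isfinite(
            self.traveled_length
        ):
            raise InvalidArgumentError("path lengths must be finite")
        if self.traveled_length < 0:
            raise InvalidArgumentError("traveled_length must be >= 0")


@dataclass(frozen=True)
class RecallTrial:
    """One verbal recall trial."""

    day: int
    trial_index: int
    list_length: int
    n_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.list_length:
            raise InvalidArgumentError("n_correct must be in [0, list_length]")


@dataclass(frozen=True)
class LearningRateResult:
    value: float
    first_component: float
    last_component: float
    n_trials: int
    task: str


def training_normalized_error(
    trial: NavTrial, threshold_factor: float = TRAINING_THRESHOLD_FACTOR
) -> tuple[float, bool]:
    """Percent distance error relative to the success threshold.

    Returns ``100 * (traveled - shortest) / (threshold_factor * shortest)``
    and whether the trial met the criterion
    (traveled <= threshold_factor * shortest).
    """
    s = trial.shortest_path_length
    if s <= 0:
        raise InvalidArgumentError("shortest_path_length must be > 0")
    value = 100.0 * (trial.traveled_length - s) / (threshold_factor * s)
    criterion = trial.traveled_length <= threshold_factor * s + 1e-12
    return value, criterion


def transfer_normalized_error(trial: NavTrial) -> float:
    """Distance error divided by the optimal distance."""
    s = trial.shortest_path_length
    if s <= 0:
        raise InvalidArgumentError("shortest_path_length must be > 0")
    value = (trial.traveled_length - s) / s
    if value < 0:
        warnings.warn(
            "traveled length below optimal; negative normalized error",
            stacklevel=2,
        )
    return value


def navigation_learning_rate(
    trials: Sequence[NavTrial], half_size: int | None = None
) -> LearningRateResult:
    """Learning rate over an ordered transfer session.

    value = −(mean(first half) − mean(last half))
            / (mean(first half) + mean(last half))
    of the normalized errors; a higher (less negative) value means more
    uniform performance across the session.
    """
    n = len(trials)
    k = half_size if half_size is not None else n // 2
    if k < 1 or n != 2 * k:
        raise InvalidArgumentError(
            f"need exactly 2 x half_size trials (got {n}, half_size {k})"
        )
    errs = np.array([transfer_normalized_error(t) for t in trials])
    first, last = errs[:k].mean(), errs[k:].mean()
    denom = first + last
    if denom == 0:
        raise UndefinedResultError("half-mean sum is zero; rate undefined")
    return LearningRateResult(
        value=-(first - last) / denom,
        first_component=first,
        last_component=last,
        n_trials=n,
        task="navigation_transfer",
    )


def verbal_learning_rate(trials: Sequence[RecallTrial]) -> LearningRateResult:
    """(last trial correct − first trial correct) / number of trials."""
    if len(trials) < 1:
        raise InvalidArgumentError("need at least one recall trial")
    first, last = trials[0].n_correct, trials[-1].n_correct
    return LearningRateResult(
        value=(last - first) / len(trials),
        first_component=float(first),
        last_component=float(last),
        n_trials=len(trials),
        task="verbal_transfer",
    )


def training_slope(
    daily_max: Sequence[tuple[int, float]],
    window: tuple[int, int] | None = None,
) -> tuple[float, float, float, float]:
    """OLS slope of daily maximum recall on day index.

    ``window`` is an inclusive (first_day, last_day) range. Returns
    (slope, intercept, t statistic vs zero slope, p value).
    """
    pts = [(d, y) for d, y in daily_max if window is None or window[0] <= d <= window[1]]
    days = np.array([d for d, _ in pts], dtype=float)
    ys = np.array([y for _, y in pts], dtype=float)
    if len(set(days)) < 2:
        raise InvalidArgumentError("need >= 2 distinct days in window")
    res = stats.linregress(days, ys)
    if np.isnan(res.stderr) or res.stderr == 0:
        # perfectly collinear points: slope exact, t unbounded
        t = np.inf if res.slope != 0 else 0.0
        p = 0.0 if res.slope != 0 else 1.0
        return float(res.slope), float(res.intercept), t, p
    t = res.slope / res.stderr
    return float(res.slope), float(res.intercept), float(t), float(res.pvalue)


# ---------------------------------------------------------------------------
# correlation machinery


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    method: str = "auto",
    normality_alpha: float = 0.05,
) -> tuple[float, float, int]:
    """Correlation with optional covariate partialling.

    ``method='auto'`` applies Shapiro–Wilk to both variables and falls
    back to Spearman when either violates normality at
    ``normality_alpha``. Covariates are removed by residualizing both
    variables on them (with intercept) before correlating.
    Returns (r, p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-D")
    n = x.size
    n_cov = 0
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise InvalidArgumentError("covariate rows must match x length")
        n_cov = covariates.shape[1]
    if n < max(4, n_cov + 3):
        raise InvalidArgumentError("too few observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedResultError("zero variance in x or y")
    if method == "auto":
        px = stats.shapiro(x).pvalue
        py = stats.shapiro(y).pvalue
        method = "pearson" if min(px, py) > normality_alpha else "spearman"
    if method not in ("pearson", "spearman"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    if covariates is not None and n_cov > 0:
        x = _residualize(x, covariates)
        y = _residualize(y, covariates)
        if np.std(x) == 0 or np.std(y) == 0:
            raise UndefinedResultError("zero variance after partialling")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return float(r), float(p), n


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int, sided: str = "two"
) -> tuple[float, float]:
    """Fisher z test for two independent correlations.

    Z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); the one-sided
    p tests r1 > r2.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise InvalidArgumentError("|r| must be < 1")
        if n <= 3:
            raise InvalidArgumentError("n must be > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    if sided == "two":
        p = 2 * stats.norm.sf(abs(z))
    elif sided == "one":
        p = stats.norm.sf(z)
    else:
        raise InvalidArgumentError("sided must be 'one' or 'two'")
    return float(z), float(p)


# ---------------------------------------------------------------------------
# tidy metric tables from log frames


def transfer_metrics_table(nav_transfer, verbal_transfer) -> "pd.DataFrame":
    """Per-participant learning-rate table from tidy transfer logs.

    Expects the column layouts written by the synthetic generator (see
    ``infoconn.synthetic.behavior``). Output columns:
    participant, group, session, task, metric, value.
    """
    import pandas as pd

    rows = []
    for (part, grp, ses), sub in nav_transfer.groupby(
        ["participant", "group", "session"], sort=True
    ):
        sub = sub.sort_values("trial")
        trials = [
            NavTrial(int(r["trial"]), float(r["optimal"]), float(r["traveled"]))
            for _, r in sub.iterrows()
        ]
        lr = navigation_learning_rate(trials)
        rows.append((part, grp, ses, "navigation_transfer", "learning_rate", lr.value))
    for (part, grp, ses), sub in verbal_transfer.groupby(
        ["participant", "group", "session"], sort=True
    ):
        sub = sub.sort_values("trial")
        trials = [
            RecallTrial(0, int(r["trial"]), int(r["list_length"]), int(r["n_correct"]))
            for _, r in sub.iterrows()
        ]
        lr = verbal_learning_rate(trials)
        rows.append((part, grp, ses, "verbal_transfer", "learning_rate", lr.value))
    return pd.DataFrame(
        rows, columns=["participant", "group", "session", "task", "metric", "value"]
    )
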