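"""Derived locomotion statistics and the two-sample validation tests.

Three per-trajectory scalars summarize the hypotheses extracted from the
network (speed stability at high speed, speed stability while
accelerating, deceleration before turns), and group differences are
tested with Welch's t-test when both samples pass a normality check and
the Brunner-Munzel test otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateSampleError,
    InsufficientSampleError,
    InvalidInputError,
    NoEventsError,
)
from .trajectories import SpeedSeries, Trajectory, to_speed_series

__all__ = [
    "DegenerateSampleError",
    "InsufficientSampleError",
    "TestResult",
    "min_speed_during_high_speed",
    "min_speed_during_acceleration",
    "acceleration_before_turns",
    "brunner_munzel",
    "welch_t",
    "normality_check",
    "select_and_test",
    "validation_table",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float
    effect_size: float
    n_x: int
    n_y: int


def _window_views(values: np.ndarray, window: int) -> np.ndarray:
    """Non-overlapping consecutive windows; trailing remainder dropped."""
    n = len(values) // window
    if n == 0:
        raise InvalidInputError(
            f"series of length {len(values)} shorter than window {window}")
    return values[: n * window].reshape(n, window)


def _top_windows(scores: np.ndarray, top_frac: float) -> np.ndarray:
    """Boolean mask of windows whose score is in the top fraction."""
    if not 0 < top_frac <= 1:
        raise InvalidInputError("top_frac must be in (0, 1]")
    k = max(1, int(round(top_frac * len(scores))))
    cutoff = np.sort(scores)[-k]
    mask = scores >= cutoff
    return mask


def min_speed_during_high_speed(s: SpeedSeries, window: int = 10,
                                top_frac: float = 0.20) -> float:
    """Mean over high-speed windows (top `top_frac` by average speed) of
    the within-window minimum speed.  High values mean the animal keeps
    its speed up while moving fast."""
    wins = _window_views(np.asarray(s.values, float), window)
    mask = _top_windows(wins.mean(axis=1), top_frac)
    return float(wins[mask].min(axis=1).mean())


def min_speed_during_acceleration(s: SpeedSeries, window: int = 10,
                                  top_frac: float = 0.20) -> float:
    """Mean within-window minimum speed over windows whose mean
    acceleration (first difference of speed) is in the top fraction.
    When acceleration is identically zero every window ties and the
    selection degenerates to all windows."""
    values = np.asarray(s.values, float)
    accel = np.diff(values, prepend=values[0])
    swins = _window_views(values, window)
    awins = _window_views(accel, window)
    mask = _top_windows(awins.mean(axis=1), top_frac)
    return float(swins[mask].min(axis=1).mean())


def acceleration_before_turns(traj: Trajectory | SpeedSeries,
                              pre_window: int = 5,
                              turn_quantile: float = 0.25) -> float:
    """Mean absolute acceleration in the `pre_window` steps before each
    turn, where turns are local minima of speed below the given speed
    quantile (a direction-change proxy)."""
    s = traj if isinstance(traj, SpeedSeries) else to_speed_series(traj)
    v = np.asarray(s.values, float)
    if len(v) < pre_window + 3:
        raise InvalidInputError("series too short for pre-turn analysis")
    interior = np.arange(1, len(v) - 1)
    is_min = (v[interior] < v[interior - 1]) & (v[interior] <= v[interior + 1])
    low = v[interior] <= np.quantile(v, turn_quantile)
    turns = interior[is_min & low]
    turns = turns[turns >= pre_window]
    if len(turns) == 0:
        raise NoEventsError("no qualifying turns in series")
    accel = np.diff(v)
    vals = [np.abs(accel[t - pre_window: t]).mean() for t in turns]
    return float(np.mean(vals))


def brunner_munzel(x, y) -> TestResult:
    """Brunner-Munzel rank test with Satterthwaite-type degrees of
    freedom; effect size is the stochastic-superiority estimate
    P(X < Y) + 0.5 P(X = Y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InsufficientSampleError("need >= 2 observations per group")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx, ry = ranks[:nx], ranks[nx:]
    rx_within = sps.rankdata(x)
    ry_within = sps.rankdata(y)
    mx, my = rx.mean(), ry.mean()
    sx2 = np.sum((rx - rx_within - mx + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((ry - ry_within - my + (ny + 1) / 2.0) ** 2) / (ny - 1)
    if sx2 == 0 and sy2 == 0:
        raise DegenerateSampleError(
            "zero rank variance (complete separation or constant data)")
    # P(X<Y) + 0.5 P(X=Y); sum-of-ranks form is exact for half-integer ranks
    effect = (ry.sum() - ny * (ny + 1) / 2.0) / (nx * ny)
    w = nx * ny * (my - mx) / ((nx + ny) * np.sqrt(nx * sx2 + ny * sy2))
    df = ((nx * sx2 + ny * sy2) ** 2
          / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1)))
    p = 2.0 * sps.t.sf(abs(w), df)
    return TestResult("brunner-munzel", float(w), float(df), float(p),
                      float(effect), nx, ny)


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance t-test; effect size r = t/sqrt(t^2+df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InsufficientSampleError("need >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateSampleError("zero variance in both samples")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    r = t / np.sqrt(t ** 2 + df)
    return TestResult("welch-t", float(t), float(df), float(p), float(r),
                      nx, ny)


def normality_check(x) -> TestResult:
    """Shapiro-Wilk normality test; small p flags non-normality."""
    x = np.asarray(x, float)
    if len(x) < 3:
        raise InsufficientSampleError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample")
    stat, p = sps.shapiro(x)
    return TestResult("shapiro-wilk", float(stat), float(len(x) - 1),
                      float(p), float("nan"), len(x), 0)


def select_and_test(x, y, alpha: float = 0.05) -> TestResult:
    """Normality-gated test selection: Welch when both samples look
    normal at level alpha, Brunner-Munzel otherwise."""
    normal = (normality_check(x).p_value > alpha
              and normality_check(y).p_value > alpha)
    return welch_t(x, y) if normal else brunner_munzel(x, y)


def validation_table(feature_name: str, x, y) -> pd.DataFrame:
    """One-row report table in the figure-caption format."""
    res = select_and_test(x, y)
    return pd.DataFrame([{
        "feature": feature_name,
        "test": res.name,
        "mean_x": float(np.mean(x)),
        "mean_y": float(np.mean(y)),
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "effect_size": res.effect_size,
        "n_x": res.n_x,
        "n_y": res.n_y,
    }])
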