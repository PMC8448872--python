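"""Synthetic two-domain, two-class locomotion cohorts.

The base process alternates low- and high-speed bouts (durations drawn
in seconds, so the two domains -- which differ in spatial scale and
sampling rate -- leave different step-level signatures), integrates the
speed along a smoothly turning heading into 2D positions, and plants a
class effect inside the high-speed bouts.  Ground truth records where
the planted signal lives so attention recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .trajectories import (
    SpeedSeries,
    Trajectory,
    normalize_series,
    to_speed_series,
    write_manifest,
    write_trajectory,
)

__all__ = [
    "EFFECT_TYPES",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "cohort_to_speed_dataset",
    "attention_recovery_score",
    "planted_fraction",
    "write_cohort",
    "read_ground_truth",
]

EFFECT_TYPES = (
    "speed-dips",            # instability during high-speed bouts
    "unstable-acceleration", # jitter while speeding up
    "pre-turn-deceleration", # abrupt braking before turns
    "high-bout-skewness",    # moment-matched skewed noise in high bouts
)


@dataclass
class CohortSpec:
    n_per_cell: int = 10
    series_len: int = 599           # speed samples; trajectory has one more
    domain_scales: tuple[float, float] = (1.0, 100.0)
    domain_rates: tuple[float, float] = (1.0, 2.0)   # Hz
    effect_type: str = "speed-dips"
    effect_magnitude: float = 1.0
    noise_std: float = 0.05
    low_speed: float = 0.2
    high_speed: float = 1.0
    high_bout_seconds: tuple[float, float] = (8.0, 20.0)
    low_bout_seconds: tuple[float, float] = (20.0, 50.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 1 or self.series_len < 20:
            raise InvalidConfigError("cohort too small")
        if min(self.domain_scales) <= 0 or min(self.domain_rates) <= 0:
            raise InvalidConfigError("scales and rates must be positive")
        if self.effect_type not in EFFECT_TYPES:
            raise InvalidConfigError(
                f"unknown effect type {self.effect_type!r}; "
                f"expected one of {EFFECT_TYPES}")
        if self.effect_magnitude < 0 or self.noise_std < 0:
            raise InvalidConfigError("magnitude and noise must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        kwargs = dict(d)
        for key in ("domain_scales", "domain_rates", "high_bout_seconds",
                    "low_bout_seconds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise InvalidConfigError(str(exc)) from exc


@dataclass
class GroundTruth:
    """Planted characteristic segments, as [start, end) speed-series
    indices per series id."""

    segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def _bout_states(spec: CohortSpec, dt: float, n_steps: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Alternating low(0)/high(1) state per step; durations in seconds."""
    states = np.zeros(n_steps, dtype=int)
    pos = 0
    state = int(rng.integers(2))
    while pos < n_steps:
        lo, hi = (spec.high_bout_seconds if state else spec.low_bout_seconds)
        steps = max(3, int(round(rng.uniform(lo, hi) / dt)))
        states[pos: pos + steps] = state
        pos += steps
        state = 1 - state
    return states


def _high_bout_intervals(states: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], states, [0]])))
    return [(int(edges[i]), int(edges[i + 1]))
            for i in range(0, len(edges), 2)]


def _apply_effect(speed: np.ndarray, base: np.ndarray, states: np.ndarray,
                  spec: CohortSpec, rng: np.random.Generator) -> None:
    """Plant the class-1 signature in place."""
    mag = spec.effect_magnitude
    if mag == 0:
        return
    bouts = _high_bout_intervals(states)
    if spec.effect_type == "speed-dips":
        for lo, hi in bouts:
            for _ in range(int(rng.integers(1, 3))):
                width = int(rng.integers(3, 8))
                if hi - lo <= width + 2:
                    continue
                start = int(rng.integers(lo + 1, hi - width - 1))
                depth = mag * rng.uniform(0.4, 0.7)
                speed[start: start + width] *= max(0.0, 1.0 - depth)
    elif spec.effect_type == "unstable-acceleration":
        for lo, hi in bouts:
            ramp = slice(lo, min(lo + 6, hi))
            n = ramp.stop - ramp.start
            speed[ramp] *= 1.0 + mag * rng.uniform(-0.5, 0.5, size=n)
    elif spec.effect_type == "pre-turn-deceleration":
        for lo, hi in bouts:
            brake = slice(max(lo, hi - 4), hi)
            n = brake.stop - brake.start
            # abrupt braking: hold speed then crash instead of easing out
            speed[brake] = speed[brake] * (1.0 - mag) \
                + mag * np.concatenate([np.full(n - 1, spec.high_speed),
                                        [0.1 * spec.high_speed]])[:n]
    elif spec.effect_type == "high-bout-skewness":
        # swap the in-bout noise for a skewed draw with matched support
        # and variance so (to first order) only the third moment moves
        for lo, hi in bouts:
            n = hi - lo
            e = np.clip(rng.exponential(1.0, size=n) - 1.0, -2.5, 2.5)
            g = np.clip(rng.standard_normal(n), -2.5, 2.5)
            blend = mag * e / 0.888 + (1.0 - mag) * g
            blend /= np.sqrt(mag ** 2 + (1.0 - mag) ** 2)
            speed[lo:hi] = base[lo:hi] + spec.noise_std * blend
    np.maximum(speed, 0.01, out=speed)


def _smooth(speed: np.ndarray, k: int = 3) -> np.ndarray:
    kernel = np.ones(k) / k
    return np.convolve(speed, kernel, mode="same")


def _make_series(spec: CohortSpec, cls: int, dom: int, rng: np.random.Generator
                 ) -> tuple[Trajectory, list[tuple[int, int]], str]:
    dt = 1.0 / spec.domain_rates[dom]
    scale = spec.domain_scales[dom]
    n = spec.series_len
    states = _bout_states(spec, dt, n, rng)
    if states.max() == 0:  # short series may sample one long low bout
        states[: max(3, int(round(spec.high_bout_seconds[0] / dt)))] = 1
    base = _smooth(np.where(states == 1, spec.high_speed,
                            spec.low_speed).astype(float))
    speed = base + spec.noise_std * rng.standard_normal(n)
    np.maximum(speed, 0.01, out=speed)
    if cls == 1:
        _apply_effect(speed, base, states, spec, rng)

    # heading: slow drift while moving fast, sharp turns while slow
    turn_sd = np.where(states == 1, 0.08, 0.6)
    heading = np.cumsum(turn_sd * rng.standard_normal(n))
    vx = speed * np.cos(heading)
    vy = speed * np.sin(heading)
    t = np.arange(n + 1) * dt
    x = scale * np.concatenate([[0.0], np.cumsum(vx * dt)])
    y = scale * np.concatenate([[0.0], np.cumsum(vy * dt)])
    sid = f"c{cls}d{dom}"
    traj = Trajectory(id=sid, t=t, x=x, y=y, class_label=cls,
                      domain_label=dom)
    return traj, _high_bout_intervals(states), sid


def generate_cohort(spec: CohortSpec) -> tuple[list[Trajectory], GroundTruth]:
    """One trajectory per (class, domain, replicate); deterministic in
    spec.seed.  Ground-truth segments are the high-speed bouts, where
    the class effect (if any) is planted."""
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(4 * spec.n_per_cell)
    trajs: list[Trajectory] = []
    truth = GroundTruth()
    k = 0
    for cls in (0, 1):
        for dom in (0, 1):
            for rep in range(spec.n_per_cell):
                rng = np.random.default_rng(children[k])
                k += 1
                traj, segments, base_id = _make_series(spec, cls, dom, rng)
                traj.id = f"{base_id}_r{rep}"
                trajs.append(traj)
                truth.segments[traj.id] = segments
    return trajs, truth


def cohort_to_speed_dataset(trajs: list[Trajectory]) -> list[SpeedSeries]:
    """Convert and z-score every trajectory (the model-ready dataset)."""
    return [normalize_series(to_speed_series(tr)) for tr in trajs]


def planted_fraction(segments: list[tuple[int, int]], length: int) -> float:
    return sum(hi - lo for lo, hi in segments) / length


def attention_recovery_score(attention: np.ndarray,
                             segments: list[tuple[int, int]]) -> float:
    """Fraction of attention mass inside the planted segments.  Uniform
    attention scores exactly the planted length fraction."""
    a = np.asarray(attention, float)
    total = a.sum()
    if total <= 0:
        raise InvalidInputError("attention mass must be positive")
    mask = np.zeros(len(a), dtype=bool)
    for lo, hi in segments:
        if lo < 0 or hi > len(a):
            raise InvalidInputError("segment outside series bounds")
        mask[lo:hi] = True
    return float(a[mask].sum() / total)


# ---------------------------------------------------------------------------
# cohort files: one trajectory CSV each + manifest + ground truth

def write_cohort(trajs: list[Trajectory], truth: GroundTruth,
                 outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trajs:
        fname = f"{tr.id}.csv"
        write_trajectory(tr, outdir / fname)
        rows.append({"id": tr.id, "class": tr.class_label,
                     "domain": tr.domain_label, "path": fname})
    write_manifest(rows, outdir / "manifest.csv")
    truth_rows = [{"id": sid, "start": lo, "end": hi}
                  for sid, segs in truth.segments.items()
                  for lo, hi in segs]
    pd.DataFrame(truth_rows, columns=["id", "start", "end"]).to_csv(
        outdir / "ground_truth.csv", index=False)
    return outdir / "manifest.csv"


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    truth = GroundTruth()
    for sid, grp in df.groupby("id"):
        truth.segments[str(sid)] = list(
            zip(grp["start"].astype(int), grp["end"].astype(int)))
    return truth
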