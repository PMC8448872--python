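"""Trajectory preprocessing: speed conversion, normalization, resampling,
segmentation, and stride extraction from ground-reaction-force records.

A trajectory is an ordered sequence of timestamped 2D positions; the
model consumes per-timestep speed series derived from it.  All file
formats are plain delimited text so cohorts round-trip losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSeriesError,
    InsufficientGaitError,
    InvalidInputError,
)

__all__ = [
    "Trajectory",
    "SpeedSeries",
    "ForceSeries",
    "to_speed_series",
    "normalize_series",
    "resample_to_length",
    "segment_trajectory",
    "gait_to_stride_series",
    "read_trajectory",
    "write_trajectory",
    "read_manifest",
    "write_manifest",
    "read_speed_series",
    "write_speed_series",
]


@dataclass
class Trajectory:
    """Timestamped 2D path with binary class and domain labels."""

    id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    class_label: int
    domain_label: int

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise InvalidInputError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise InvalidInputError("trajectory needs at least 2 points")
        if np.any(np.diff(self.t) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if self.class_label not in (0, 1) or self.domain_label not in (0, 1):
            raise InvalidInputError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())


@dataclass
class SpeedSeries:
    """Per-timestep speed values; length is one less than the trajectory."""

    id: str
    values: np.ndarray
    class_label: int
    domain_label: int
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise InvalidInputError("speed series must be 1D and nonempty")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ForceSeries:
    """Summed vertical ground-reaction force per foot, fixed sampling rate."""

    id: str
    left: np.ndarray
    right: np.ndarray
    rate: float
    class_label: int = 0
    domain_label: int = 0

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.rate <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if len(self.left) == 0 or len(self.right) == 0:
            raise InvalidInputError("both feet need force samples")


def to_speed_series(traj: Trajectory) -> SpeedSeries:
    """Convert positions to speeds: Euclidean step distance over step time."""
    dt = np.diff(traj.t)
    dist = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return SpeedSeries(
        id=traj.id,
        values=dist / dt,
        class_label=traj.class_label,
        domain_label=traj.domain_label,
        normalized=False,
    )


def normalize_series(s: SpeedSeries, tol: float = 1e-12) -> SpeedSeries:
    """Per-series z-score using the population standard deviation."""
    if len(s) < 2:
        raise InvalidInputError("need at least 2 values to normalize")
    std = float(np.std(s.values))
    if std < tol:
        raise DegenerateSeriesError(f"series {s.id!r} has zero variance")
    return replace(s, values=(s.values - s.values.mean()) / std,
                   normalized=True)


def resample_to_length(s: SpeedSeries, target_len: int) -> SpeedSeries:
    """Undersample by even-stride index selection, keeping the first index."""
    n = len(s)
    if target_len < 1 or target_len > n:
        raise InvalidInputError(
            f"target length {target_len} outside [1, {n}]")
    idx = (np.arange(target_len) * n) // target_len
    return replace(s, values=s.values[idx])


def segment_trajectory(traj: Trajectory, segment_seconds: float,
                       min_movement: float = 0.0) -> list[Trajectory]:
    """Split into consecutive fixed-duration segments, dropping both the
    trailing remainder and segments whose path length is below
    ``min_movement`` (no-movement exclusion)."""
    if segment_seconds <= 0:
        raise InvalidInputError("segment duration must be positive")
    t0 = traj.t[0]
    n_seg = int(math.floor(traj.duration / segment_seconds))
    out: list[Trajectory] = []
    for k in range(n_seg):
        lo = t0 + k * segment_seconds
        hi = lo + segment_seconds
        # half-open window, except final segment keeps its right endpoint
        mask = (traj.t >= lo) & ((traj.t < hi) | (k == n_seg - 1) & (traj.t == hi))
        if mask.sum() < 2:
            continue
        seg = Trajectory(
            id=f"{traj.id}_seg{k}",
            t=traj.t[mask],
            x=traj.x[mask],
            y=traj.y[mask],
            class_label=traj.class_label,
            domain_label=traj.domain_label,
        )
        if seg.path_length() >= min_movement:
            out.append(seg)
    return out


def _contact_onsets(force: np.ndarray, rate: float,
                    threshold: float) -> np.ndarray:
    """Timestamps of upward threshold crossings of a force signal."""
    above = force >= threshold
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    return onsets / rate


def gait_to_stride_series(f: ForceSeries,
                          contact_threshold: float | None = None
                          ) -> SpeedSeries:
    """Stride times from per-foot contact onsets, merged across feet in
    timestamp order.  Stride time is the interval between consecutive
    onsets of the same foot; the default threshold is 5% of the per-foot
    maximum force."""
    events: list[tuple[float, float]] = []
    for foot in (f.left, f.right):
        thr = contact_threshold
        if thr is None:
            thr = 0.05 * float(foot.max())
        if thr <= 0:
            raise InsufficientGaitError("contact threshold must be positive")
        onsets = _contact_onsets(foot, f.rate, thr)
        if len(onsets) < 2:
            raise InsufficientGaitError(
                f"foot has {len(onsets)} contact onsets; need >= 2")
        strides = np.diff(onsets)
        events.extend(zip(onsets[1:], strides))
    events.sort(key=lambda e: e[0])
    return SpeedSeries(
        id=f.id,
        values=np.array([s for _, s in events]),
        class_label=f.class_label,
        domain_label=f.domain_label,
        normalized=False,
    )


# ---------------------------------------------------------------------------
# plain-text I/O

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(
        path, index=False)


def read_trajectory(path: str | Path, id: str, class_label: int,
                    domain_label: int) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(id=id, t=df["t"].to_numpy(), x=df["x"].to_numpy(),
                      y=df["y"].to_numpy(), class_label=class_label,
                      domain_label=domain_label)


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Manifest rows: id, class, domain, path."""
    pd.DataFrame(rows, columns=["id", "class", "domain", "path"]).to_csv(
        path, index=False)


def read_manifest(path: str | Path) -> list[dict]:
    df = pd.read_csv(path)
    for col in ("id", "class", "domain", "path"):
        if col not in df.columns:
            raise InvalidInputError(f"manifest missing column {col!r}")
    return df.to_dict("records")


def write_speed_series(s: SpeedSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# id={s.id} class={s.class_label} "
                 f"domain={s.domain_label} normalized={int(s.normalized)}\n")
        for v in s.values:
            fh.write(f"{v:.12g}\n")


def read_speed_series(path: str | Path) -> SpeedSeries:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# "):
            raise InvalidInputError(f"{path}: missing header line")
        meta = dict(kv.split("=") for kv in header[2:].split())
        values = np.array([float(line) for line in fh if line.strip()])
    return SpeedSeries(
        id=meta["id"],
        values=values,
        class_label=int(meta["class"]),
        domain_label=int(meta["domain"]),
        normalized=bool(int(meta["normalized"])),
    )
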