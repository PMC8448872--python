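"""Surrogate explanations of attention and classification.

Per-timestep interpretable features (speed, acceleration and their
centered rolling statistics) are min-max normalized within each
trajectory, labeled by thresholding attention at 1/l, and fed to
depth-limited decision trees: one predicting attended-vs-none per
timestep, one predicting class from attention-weighted feature averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateLabelsError, InvalidConfigError, InvalidInputError
from .trajectories import SpeedSeries

__all__ = [
    "DEFAULT_WINDOWS",
    "WindowFeatureMatrix",
    "SurrogateTree",
    "label_attention",
    "attention_threshold",
    "extract_window_features",
    "weighted_feature_vector",
    "fit_attention_tree",
    "fit_classification_tree",
    "export_highlights",
]

DEFAULT_WINDOWS = (5, 11, 21)

_ROLLING_STATS = ("mean", "min", "max", "std", "skew", "kurt")


@dataclass
class WindowFeatureMatrix:
    """Per-timestep feature rows for one series, min-max scaled in [0, 1]."""

    values: np.ndarray            # (l, n_features)
    feature_names: list[str]
    windows: tuple[int, ...]

    def __post_init__(self):
        if self.values.shape[1] != len(self.feature_names):
            raise InvalidInputError("feature names must match columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InvalidInputError("feature names must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def attention_threshold(length: int) -> float:
    """Uniform-attention level 1/l; a softmax output can only be
    informative where it exceeds this."""
    return 1.0 / length


def label_attention(a: np.ndarray) -> np.ndarray:
    """Boolean per-timestep labels: attended iff strictly above 1/l."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or len(a) < 1:
        raise InvalidInputError("attention vector must be 1D and nonempty")
    return a > attention_threshold(len(a))


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi - lo == 0:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def extract_window_features(s: SpeedSeries,
                            windows: tuple[int, ...] = DEFAULT_WINDOWS
                            ) -> WindowFeatureMatrix:
    """Centered rolling statistics of speed and acceleration at each
    window length, plus the raw signals and a local-minimum flag; edges
    are truncated (min_periods=1) and zero-variance statistics map to 0."""
    length = len(s)
    for w in windows:
        if w < 2 or w > length:
            raise InvalidConfigError(
                f"window {w} incompatible with series length {length}")
    speed = pd.Series(s.values)
    accel = speed.diff().fillna(0.0)
    cols: dict[str, pd.Series] = {"speed": speed, "accel": accel}
    v = s.values
    local_min = np.zeros(length)
    local_min[1:-1] = (v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:])
    cols["local_min"] = pd.Series(local_min)
    for base_name, base in (("speed", speed), ("accel", accel)):
        for w in windows:
            roll = base.rolling(w, center=True, min_periods=1)
            std = roll.std()
            for stat in _ROLLING_STATS:
                col = getattr(roll, stat)()
                if stat in ("skew", "kurt"):  # 0 for degenerate windows
                    col = col.where(std > 1e-12, 0.0)
                cols[f"{base_name}_{stat}_w{w}"] = col
    frame = pd.DataFrame(cols).replace([np.inf, -np.inf], 0.0).fillna(0.0)
    values = np.column_stack([_minmax(frame[c].to_numpy())
                              for c in frame.columns])
    return WindowFeatureMatrix(values=values,
                               feature_names=list(frame.columns),
                               windows=tuple(windows))


def weighted_feature_vector(features: WindowFeatureMatrix,
                            attention: np.ndarray) -> np.ndarray:
    """Attention-weighted average over timesteps (weights sum to 1)."""
    a = np.asarray(attention, dtype=float)
    if len(a) != features.values.shape[0]:
        raise InvalidInputError("attention length mismatch")
    return a @ features.values


@dataclass
class SurrogateTree:
    """Fitted decision tree plus the vocabulary needed to read it."""

    tree: DecisionTreeClassifier
    feature_names: list[str]
    class_names: list[str]

    @property
    def root_feature(self) -> str:
        return self.feature_names[self.tree.tree_.feature[0]]

    @property
    def root_threshold(self) -> float:
        return float(self.tree.tree_.threshold[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree.predict(X)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(self.tree.score(X, y))

    def report(self, max_depth: int = 2) -> str:
        """Indented text rendering of the top of the tree; values below
        a node's threshold descend to the left child."""
        t = self.tree.tree_
        lines: list[str] = []

        def walk(node: int, depth: int):
            indent = "  " * depth
            counts = t.value[node][0] * t.weighted_n_node_samples[node]
            hist = "/".join(f"{c:.0f}" for c in counts)
            if t.children_left[node] == -1 or depth >= max_depth:
                label = self.class_names[int(np.argmax(t.value[node][0]))]
                lines.append(f"{indent}leaf: {label} [{hist}]")
                return
            name = self.feature_names[t.feature[node]]
            lines.append(f"{indent}{name} < {t.threshold[node]:.4g} [{hist}]")
            walk(t.children_left[node], depth + 1)
            walk(t.children_right[node], depth + 1)

        walk(0, 0)
        return "\n".join(lines)


def _fit_tree(X: np.ndarray, y: np.ndarray, class_names: list[str],
              feature_names: list[str], *, max_depth: int,
              min_samples_leaf: int, seed: int) -> SurrogateTree:
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("need both label values to fit a tree")
    clf = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                 min_samples_leaf=min_samples_leaf,
                                 random_state=seed)
    clf.fit(X, y)
    return SurrogateTree(tree=clf, feature_names=feature_names,
                         class_names=class_names)


def fit_attention_tree(features: list[WindowFeatureMatrix],
                       attention: list[np.ndarray], *, max_depth: int = 4,
                       min_samples_leaf: int = 5, seed: int = 0
                       ) -> SurrogateTree:
    """Pool per-timestep rows across series and fit attended-vs-none."""
    if len(features) != len(attention) or not features:
        raise InvalidInputError("need matching, nonempty feature/attention lists")
    X = np.vstack([f.values for f in features])
    y = np.concatenate([label_attention(a) for a in attention]).astype(int)
    return _fit_tree(X, y, ["none", "attended"], features[0].feature_names,
                     max_depth=max_depth, min_samples_leaf=min_samples_leaf,
                     seed=seed)


def fit_classification_tree(features: list[WindowFeatureMatrix],
                            attention: list[np.ndarray],
                            class_labels: np.ndarray, *, max_depth: int = 4,
                            min_samples_leaf: int = 5, seed: int = 0
                            ) -> SurrogateTree:
    """One attention-weighted feature vector per series, fitted to class."""
    if not (len(features) == len(attention) == len(class_labels)) or not features:
        raise InvalidInputError("need aligned, nonempty inputs")
    X = np.vstack([weighted_feature_vector(f, a)
                   for f, a in zip(features, attention)])
    y = np.asarray(class_labels, dtype=int)
    return _fit_tree(X, y, ["class0", "class1"], features[0].feature_names,
                     max_depth=max_depth, min_samples_leaf=min_samples_leaf,
                     seed=seed)


def export_highlights(s: SpeedSeries, attention: np.ndarray,
                      path: str | Path) -> None:
    """Per-timestep (t, speed, attention, attended) table behind the
    highlighted time-series plots."""
    a = np.asarray(attention, dtype=float)
    if len(a) != len(s):
        raise InvalidInputError("attention length mismatch")
    pd.DataFrame({
        "t": np.arange(len(s)),
        "speed": s.values,
        "attention": a,
        "attended": label_attention(a).astype(int),
    }).to_csv(path, index=False)
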