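"""Three-phase adversarial training.

Each epoch iterates three minimizations, all with Adam and the current
gradient-reversal strength mu:

  phase 1: mean class BCE minus lambda1 x mean per-timestep domain BCE
           (updates feature, attention, class and 2nd-domain parameters)
  phase 2: mean per-series domain BCE through the 1st domain head
           (updates feature, attention and 1st-domain parameters)
  phase 3: mean class BCE minus lambda2 x mean per-series domain BCE
           (updates feature, attention, class and 1st-domain parameters)

The reversal layer carries the minus sign at gradient time: the scalar
propagated backward is (class BCE + lambda x domain BCE) so the domain
heads descend their own loss while reversed gradients push the shared
blocks to *worsen* domain prediction.  The reported loss value is the
signed objective as written above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .errors import InvalidConfigError, InvalidDatasetError, InvalidInputError
from .network import ForwardOutputs, ModelState, NetworkConfig, forward, init_model
from .trajectories import SpeedSeries

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "PhaseLoss",
    "bce",
    "loss_phase1",
    "loss_phase2",
    "loss_phase3",
    "mu_schedule",
    "train",
    "evaluate",
    "stratified_split",
]

EPS = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 100
    lambda1: float = 1.0
    lambda2: float = 1.0
    mu_max: float = 1.0            # L, the upper bound of mu
    alpha: float = 1.4
    beta: float = 10.0
    t1: float | None = None        # defaults to epochs / 10
    t2: float | None = None        # defaults to epochs / 1.2
    learning_rate: float = 1e-3
    batch_size: int = 16
    val_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.t1 is None:
            self.t1 = self.epochs / 10.0
        if self.t2 is None:
            self.t2 = self.epochs / 1.2
        if not (self.t1 < self.t2 <= self.epochs):
            raise InvalidConfigError("need t1 < t2 <= epochs")
        if min(self.lambda1, self.lambda2, self.mu_max) < 0:
            raise InvalidConfigError("lambda1, lambda2, mu_max must be >= 0")


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    loss_phase1: list[float] = field(default_factory=list)
    loss_phase2: list[float] = field(default_factory=list)
    loss_phase3: list[float] = field(default_factory=list)
    class_loss: list[float] = field(default_factory=list)
    class_acc: list[float] = field(default_factory=list)
    domain1_acc: list[float] = field(default_factory=list)
    domain2_acc: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epochs, "mu": self.mu,
            "loss_phase1": self.loss_phase1, "loss_phase2": self.loss_phase2,
            "loss_phase3": self.loss_phase3, "class_loss": self.class_loss,
            "class_acc": self.class_acc, "domain1_acc": self.domain1_acc,
            "domain2_acc": self.domain2_acc,
        })


@dataclass
class PhaseLoss:
    """Reported objective value plus the graph node driving backprop."""

    value: float
    node: Tensor
    class_loss: float = float("nan")
    domain_loss: float = float("nan")

    def __float__(self) -> float:
        return self.value


def bce(p, y) -> float:
    """Binary cross-entropy on probabilities, clipped at 1e-7; returns
    the mean over elements."""
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=float)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def _bce_node(p: Tensor, y: np.ndarray) -> Tensor:
    """Mean BCE as a graph node; y is broadcast against p."""
    y = np.broadcast_to(np.asarray(y, dtype=float), p.data.shape)
    pc = ad.clip(p, EPS, 1.0 - EPS)
    one = ad.constant(np.ones_like(y))
    term = ad.add(
        ad.mul(ad.constant(y), ad.log(pc)),
        ad.mul(ad.constant(1.0 - y), ad.log(ad.sub(one, pc))),
    )
    return ad.scale(ad.mean_all(term), -1.0)


def _check_batch(x, y, d):
    if len(x) == 0:
        raise InvalidInputError("empty batch")
    if not (len(x) == len(y) == len(d)):
        raise InvalidInputError("batch arrays must align")


def _forward_batch(batch, model: ModelState, mu: float, training: bool,
                   dropout_rng) -> tuple[ForwardOutputs, np.ndarray, np.ndarray]:
    x, y, d = batch
    _check_batch(x, y, d)
    out = forward(model, np.asarray(x, float), training=training, mu=mu,
                  dropout_rng=dropout_rng)
    return out, np.asarray(y, float), np.asarray(d, float)


def loss_phase1(batch, model: ModelState, lambda1: float, *, mu: float = 0.0,
                training: bool = False, dropout_rng=None) -> PhaseLoss:
    """Class BCE minus lambda1 x per-timestep domain BCE (2nd head)."""
    out, y, d = _forward_batch(batch, model, mu, training, dropout_rng)
    l_c = _bce_node(out.class_prob_node, y)
    l_d2 = _bce_node(out.domain_series_node, d[:, None])
    node = ad.add(l_c, ad.scale(l_d2, lambda1))
    value = float(l_c.data) - lambda1 * float(l_d2.data)
    return PhaseLoss(value, node, float(l_c.data), float(l_d2.data))


def loss_phase2(batch, model: ModelState, *, mu: float = 0.0,
                training: bool = False, dropout_rng=None) -> PhaseLoss:
    """Per-series domain BCE through the 1st domain head."""
    out, y, d = _forward_batch(batch, model, mu, training, dropout_rng)
    l_d1 = _bce_node(out.domain_prob_node, d)
    return PhaseLoss(float(l_d1.data), l_d1,
                     float("nan"), float(l_d1.data))


def loss_phase3(batch, model: ModelState, lambda2: float, *, mu: float = 0.0,
                training: bool = False, dropout_rng=None) -> PhaseLoss:
    """Class BCE minus lambda2 x per-series domain BCE (1st head)."""
    out, y, d = _forward_batch(batch, model, mu, training, dropout_rng)
    l_c = _bce_node(out.class_prob_node, y)
    l_d1 = _bce_node(out.domain_prob_node, d)
    node = ad.add(l_c, ad.scale(l_d1, lambda2))
    value = float(l_c.data) - lambda2 * float(l_d1.data)
    return PhaseLoss(value, node, float(l_c.data), float(l_d1.data))


def mu_schedule(i: float, cfg: TrainConfig) -> float:
    """Reversal strength at (real-valued) epoch i: zero before t1, a
    sigmoidal ramp on [t1, t2), the upper bound afterwards."""
    if i < 0:
        raise InvalidInputError("epoch index must be nonnegative")
    L, a, b = cfg.mu_max, cfg.alpha, cfg.beta
    if i < cfg.t1:
        return 0.0
    if i >= cfg.t2:
        return float(L)
    frac = (i - cfg.t1) / (cfg.t2 - cfg.t1)
    return (L + 1.0) / (L * a ** (-b * frac) + 1.0) - 1.0


def stratified_split(y: np.ndarray, d: np.ndarray, val_frac: float,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Index split stratified by the (class, domain) cell."""
    train_idx, val_idx = [], []
    y = np.asarray(y)
    d = np.asarray(d)
    for cls in np.unique(y):
        for dom in np.unique(d):
            cell = np.flatnonzero((y == cls) & (d == dom))
            cell = rng.permutation(cell)
            n_val = int(round(val_frac * len(cell)))
            val_idx.extend(cell[:n_val])
            train_idx.extend(cell[n_val:])
    return np.sort(np.array(train_idx, int)), np.sort(np.array(val_idx, int))


def _dataset_arrays(dataset: list[SpeedSeries]):
    if not dataset:
        raise InvalidDatasetError("empty dataset")
    lengths = {len(s) for s in dataset}
    if len(lengths) != 1:
        raise InvalidDatasetError(f"mixed series lengths: {sorted(lengths)}")
    x = np.stack([s.values for s in dataset])
    y = np.array([s.class_label for s in dataset], float)
    d = np.array([s.domain_label for s in dataset], float)
    if len(np.unique(y)) < 2 or len(np.unique(d)) < 2:
        raise InvalidDatasetError("need both classes and both domains")
    return x, y, d


def evaluate(model: ModelState, x: np.ndarray, y: np.ndarray,
             d: np.ndarray) -> dict[str, float]:
    out = forward(model, x, training=False)
    return {
        "class_loss": bce(out.class_prob, y),
        "class_acc": float(np.mean((out.class_prob > 0.5) == (y > 0.5))),
        "domain1_acc": float(np.mean((out.domain_prob > 0.5) == (d > 0.5))),
        "domain2_acc": float(np.mean(
            (out.domain_prob_series > 0.5) == (d[:, None] > 0.5))),
    }


def train(dataset: list[SpeedSeries], net_cfg: NetworkConfig,
          cfg: TrainConfig) -> tuple[ModelState, TrainHistory]:
    """Iterate the three phases for cfg.epochs epochs; deterministic
    given cfg.seed.  History metrics are measured on the held-out split
    (falling back to the training split when val_frac leaves it empty)."""
    x, y, d = _dataset_arrays(dataset)
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = stratified_split(y, d, cfg.val_frac, rng)
    if len(val_idx) == 0:
        val_idx = train_idx
    xt, yt, dt = x[train_idx], y[train_idx], d[train_idx]
    xv, yv, dv = x[val_idx], y[val_idx], d[val_idx]

    model = init_model(net_cfg, seed=cfg.seed)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    opts = {
        1: Adam(model.groups(["theta_f", "theta_a", "theta_c", "theta_d2"]),
                lr=cfg.learning_rate),
        2: Adam(model.groups(["theta_f", "theta_a", "theta_d1"]),
                lr=cfg.learning_rate),
        3: Adam(model.groups(["theta_f", "theta_a", "theta_c", "theta_d1"]),
                lr=cfg.learning_rate),
    }
    history = TrainHistory()
    n = len(xt)
    for epoch in range(cfg.epochs):
        mu = mu_schedule(epoch, cfg)
        order = rng.permutation(n)
        phase_vals = {1: [], 2: [], 3: []}
        for phase in (1, 2, 3):
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo: lo + cfg.batch_size]
                batch = (xt[idx], yt[idx], dt[idx])
                if phase == 1:
                    loss = loss_phase1(batch, model, cfg.lambda1, mu=mu,
                                       training=True, dropout_rng=drop_rng)
                elif phase == 2:
                    loss = loss_phase2(batch, model, mu=mu,
                                       training=True, dropout_rng=drop_rng)
                else:
                    loss = loss_phase3(batch, model, cfg.lambda2, mu=mu,
                                       training=True, dropout_rng=drop_rng)
                for p in model.all_params():
                    p.grad = None
                loss.node.backward()
                opts[phase].step()
                phase_vals[phase].append(loss.value)
        metrics = evaluate(model, xv, yv, dv)
        history.epochs.append(epoch)
        history.mu.append(mu)
        history.loss_phase1.append(float(np.mean(phase_vals[1])))
        history.loss_phase2.append(float(np.mean(phase_vals[2])))
        history.loss_phase3.append(float(np.mean(phase_vals[3])))
        history.class_loss.append(metrics["class_loss"])
        history.class_acc.append(metrics["class_acc"])
        history.domain1_acc.append(metrics["domain1_acc"])
        history.domain2_acc.append(metrics["domain2_acc"])
    return model, history
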