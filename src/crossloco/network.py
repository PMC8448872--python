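"""The attention-based domain-adversarial network.

Architecture (forward pass over a batch of speed series):

  feature block     two stride-1 "same" 1D convolutions (relu, dropout)
  attention block   two stride-1 "same" 1D convolutions (relu) -> Z,
                    then a = softmax_t(W_a2 . tanh(W_a1 Z^T)) with no bias
  2nd domain head   per-timestep: grad-reverse(Z) -> dense tanh -> softmax
  pooling           attention-weighted sum over time of feature-block output
  class head        dense tanh -> dense softmax on the pooled vector
  1st domain head   grad-reverse(pooled) -> dense tanh -> dense softmax

Binary cross-entropy is computed on the positive-class softmax output.
Parameters are grouped as theta_f / theta_a / theta_c / theta_d1 / theta_d2
so each training phase can update its own subset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, grad_reverse  # re-exported  # noqa: F401
from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "NetworkConfig",
    "ModelState",
    "ForwardOutputs",
    "grad_reverse",
    "compute_attention",
    "forward",
    "init_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    input_len: int
    n_filters: int = 64
    filter_width: int = 5
    attn_hidden: int = 64
    head_hidden: int = 64
    dropout_rate: float = 0.5

    def __post_init__(self):
        if self.input_len < 1 or self.n_filters < 1 or self.filter_width < 1:
            raise InvalidConfigError("sizes must be positive")
        if self.attn_hidden < 1 or self.head_hidden < 1:
            raise InvalidConfigError("hidden sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidConfigError("dropout rate must be in [0, 1)")


# parameter group -> list of parameter names, fixed ordering for checkpoints
_GROUPS = {
    "theta_f": ["f_w1", "f_b1", "f_w2", "f_b2"],
    "theta_a": ["a_w1", "a_b1", "a_w2", "a_b2", "w_a1", "w_a2"],
    "theta_c": ["c_w1", "c_b1", "c_w2", "c_b2"],
    "theta_d1": ["d1_w1", "d1_b1", "d1_w2", "d1_b2"],
    "theta_d2": ["d2_w1", "d2_b1", "d2_w2", "d2_b2"],
}


@dataclass
class ModelState:
    """All trainable tensors, addressable by group for phase-wise updates."""

    config: NetworkConfig
    params: dict[str, Tensor]
    rng_seed: int

    def group(self, name: str) -> list[Tensor]:
        return [self.params[k] for k in _GROUPS[name]]

    def groups(self, names: list[str]) -> list[Tensor]:
        out: list[Tensor] = []
        for n in names:
            out.extend(self.group(n))
        return out

    def all_params(self) -> list[Tensor]:
        return self.groups(list(_GROUPS))

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: ad.parameter(v.data.copy())
                    for k, v in self.params.items()},
            rng_seed=self.rng_seed,
        )


@dataclass
class ForwardOutputs:
    class_prob: np.ndarray          # (B,) positive-class probability
    domain_prob: np.ndarray         # (B,) via 1st domain head
    domain_prob_series: np.ndarray  # (B, l) via 2nd domain head
    attention: np.ndarray           # (B, l), rows sum to 1
    Z: np.ndarray                   # (B, l, C) attention-block features
    # graph nodes kept for loss construction during training
    class_prob_node: Tensor = field(repr=False, default=None)
    domain_prob_node: Tensor = field(repr=False, default=None)
    domain_series_node: Tensor = field(repr=False, default=None)
    attention_node: Tensor = field(repr=False, default=None)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def init_model(cfg: NetworkConfig, seed: int = 0) -> ModelState:
    rng = np.random.default_rng(seed)
    nf, F, ah, hh = (cfg.n_filters, cfg.filter_width,
                     cfg.attn_hidden, cfg.head_hidden)
    p: dict[str, np.ndarray] = {}
    for prefix in ("f", "a"):  # two conv layers per block
        p[f"{prefix}_w1"] = _glorot(rng, (F, 1, nf), F, F * nf)
        p[f"{prefix}_b1"] = np.zeros(nf)
        p[f"{prefix}_w2"] = _glorot(rng, (F, nf, nf), F * nf, F * nf)
        p[f"{prefix}_b2"] = np.zeros(nf)
    p["w_a1"] = _glorot(rng, (ah, nf), nf, ah)   # attention dense, no bias
    p["w_a2"] = _glorot(rng, (1, ah), ah, 1)
    for prefix in ("c", "d1", "d2"):  # two-dense heads, tanh then softmax
        p[f"{prefix}_w1"] = _glorot(rng, (nf, hh), nf, hh)
        p[f"{prefix}_b1"] = np.zeros(hh)
        p[f"{prefix}_w2"] = _glorot(rng, (hh, 2), hh, 2)
        p[f"{prefix}_b2"] = np.zeros(2)
    return ModelState(config=cfg,
                      params={k: ad.parameter(v) for k, v in p.items()},
                      rng_seed=seed)


def compute_attention(Z: Tensor, w_a1: Tensor, w_a2: Tensor) -> Tensor:
    """a = softmax over time of W_a2 . tanh(W_a1 Z^T).

    Z: (B, l, C); W_a1: (h, C); W_a2: (1, h); result (B, l).
    """
    if Z.data.ndim != 3 or w_a1.data.shape[1] != Z.data.shape[2] \
            or w_a2.data.shape[1] != w_a1.data.shape[0]:
        raise InvalidConfigError("attention weight shapes incompatible with Z")
    hidden = ad.tanh(ad.dense(Z, _transposed(w_a1)))
    scores = ad.dense(hidden, _transposed(w_a2))  # (B, l, 1)
    scores = ad.sum_axis(scores, axis=2)          # (B, l)
    return ad.softmax(scores, axis=1)


def _transposed(w: Tensor) -> Tensor:
    """View a (out, in) weight as (in, out) for the dense op, sharing grads."""
    out_data = w.data.T

    def backward(g):
        if w.requires_grad:
            w._accumulate(g.T)

    return Tensor(out_data, (w,), backward)


def _two_dense_head(x: Tensor, w1, b1, w2, b2) -> Tensor:
    """dense -> tanh -> dense -> softmax; returns positive-class column."""
    h = ad.tanh(ad.dense(x, w1, b1))
    return ad.softmax(ad.dense(h, w2, b2), axis=-1)


def forward(model: ModelState, batch: np.ndarray, *, training: bool = False,
            mu: float = 0.0,
            dropout_rng: np.random.Generator | None = None) -> ForwardOutputs:
    """Run the full network on a batch of speed series (B, l)."""
    cfg = model.config
    batch = np.asarray(batch, dtype=float)
    if batch.ndim == 1:
        batch = batch[None, :]
    if batch.shape[1] != cfg.input_len:
        raise InvalidInputError(
            f"series length {batch.shape[1]} != configured {cfg.input_len}")
    if training and dropout_rng is None:
        dropout_rng = np.random.default_rng(model.rng_seed)
    p = model.params
    x = ad.constant(batch[:, :, None])  # (B, l, 1)

    # feature extraction block
    h = ad.relu(ad.conv1d_same(x, p["f_w1"], p["f_b1"]))
    h = ad.dropout(h, cfg.dropout_rate, dropout_rng, training)
    h = ad.relu(ad.conv1d_same(h, p["f_w2"], p["f_b2"]))
    h = ad.dropout(h, cfg.dropout_rate, dropout_rng, training)

    # attention computation block
    z = ad.relu(ad.conv1d_same(x, p["a_w1"], p["a_b1"]))
    z = ad.relu(ad.conv1d_same(z, p["a_w2"], p["a_b2"]))
    attn = compute_attention(z, p["w_a1"], p["w_a2"])  # (B, l)

    # 2nd domain predictor: per-timestep, through gradient reversal
    z_rev = grad_reverse(z, mu)
    d2 = _two_dense_head(z_rev, p["d2_w1"], p["d2_b1"],
                         p["d2_w2"], p["d2_b2"])  # (B, l, 2)

    # attention-weighted pooling of extracted features
    pooled = ad.weighted_time_pool(attn, h)  # (B, C)

    c = _two_dense_head(pooled, p["c_w1"], p["c_b1"], p["c_w2"], p["c_b2"])
    pooled_rev = grad_reverse(pooled, mu)
    d1 = _two_dense_head(pooled_rev, p["d1_w1"], p["d1_b1"],
                         p["d1_w2"], p["d1_b2"])

    def pos(t: Tensor) -> Tensor:  # positive-class probability column
        return ad.sum_axis(mul_select(t), axis=-1)

    def mul_select(t: Tensor) -> Tensor:
        sel = np.zeros(t.data.shape[-1])
        sel[1] = 1.0
        return ad.mul(t, ad.constant(sel))

    c_pos = pos(c)
    d1_pos = pos(d1)
    d2_pos = pos(d2)

    return ForwardOutputs(
        class_prob=c_pos.data.copy(),
        domain_prob=d1_pos.data.copy(),
        domain_prob_series=d2_pos.data.copy(),
        attention=attn.data.copy(),
        Z=z.data.copy(),
        class_prob_node=c_pos,
        domain_prob_node=d1_pos,
        domain_series_node=d2_pos,
        attention_node=attn,
    )


# ---------------------------------------------------------------------------
# checkpoints (plain JSON so they survive text-only transport)

def save_checkpoint(model: ModelState, path: str | Path) -> None:
    payload = {
        "config": asdict(model.config),
        "rng_seed": model.rng_seed,
        "params": {k: v.data.tolist() for k, v in model.params.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> ModelState:
    payload = json.loads(Path(path).read_text())
    cfg = NetworkConfig(**payload["config"])
    params = {k: ad.parameter(np.array(v, dtype=float))
              for k, v in payload["params"].items()}
    if set(params) != {n for names in _GROUPS.values() for n in names}:
        raise InvalidConfigError("checkpoint parameter set mismatch")
    return ModelState(config=cfg, params=params,
                      rng_seed=int(payload["rng_seed"]))
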