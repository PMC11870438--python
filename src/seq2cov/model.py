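"""Architecture assembly, the Poisson-multinomial coverage loss,
equivariance diagnostics, the optimizer schedule, and the training loop.

A model is a convolutional trunk (one-hot DNA → embedding over 32-bp
bins) followed by a configurable stack of residual layers — bidirectional
Mamba, gated long-convolution (Hyena), or U-Net-wrapped attention,
possibly striped — and a per-track affine + softplus head producing
strictly positive predicted rates.

The loss couples a Poisson term on each track's total count with a
multinomial term on the distribution of counts across positions; with
multinomial weight 1 this is exactly (up to a constant in the
predictions) a sum of independent per-bin Poisson negative
log-likelihoods, and the training default upweights the multinomial term
by a factor of four.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Callable, Sequence

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor, softplus
from .attention import AttentionConfig, AttentionLayer, UNetWrap
from .convnet import HyenaConfig, HyenaLayer, Trunk
from .nn import Linear, Module
from .seqdata import SequenceWindow, TrackMeta, _pair_permutation, revcomp_onehot
from .ssm import MambaLayer, SSMConfig

__all__ = ["MambaSpec", "HyenaSpec", "AttnSpec", "ModelConfig", "TrainConfig",
           "Model", "build_model", "poisson_multinomial_loss",
           "poisson_multinomial_terms", "equivariance_gap",
           "equivariance_penalty", "lr_schedule", "clip_gradients", "Adam",
           "train", "TrainResult", "desk_model_config", "desk_train_config"]


# -------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class MambaSpec:
    N: int = 8
    E: int = 1
    bidirectional: bool = True


@dataclasses.dataclass
class HyenaSpec:
    order: int = 2
    channel_mixing: bool = False
    siren_init: str = "inv_length"


@dataclasses.dataclass
class AttnSpec:
    pos_mode: str = "NONE"
    unet_rounds: int = 1        # 2 for the transformer-only path (128-bp res)
    chunk_len: int | None = None
    heads: int = 4
    d_qk: int = 64


LayerSpec = MambaSpec | HyenaSpec | AttnSpec


@dataclasses.dataclass
class ModelConfig:
    """Full architecture description.

    ``stack`` is the ordered list of residual layers applied after the
    trunk; striped architectures simply interleave specs, e.g.
    ``[MambaSpec(), MambaSpec(), AttnSpec(pos_mode="ROPE")] * 2``.
    Output bins = window_len / bin_width.
    """

    n_tracks: int
    d_model: int = 768
    window_len: int = 393_216
    bin_width: int = 32
    trunk_blocks: int = 5
    trunk_first_width: int = 15
    trunk_width: int = 5
    trunk_channels: list[int] | None = None   # None → geometric 4 → d_model
    stack: list[LayerSpec] = dataclasses.field(default_factory=list)
    rate_floor: float = 1e-6

    def __post_init__(self):
        if self.window_len % (2 ** self.trunk_blocks) != 0:
            raise ValueError("window_len must be divisible by 2^trunk_blocks")
        if self.window_len // (2 ** self.trunk_blocks) != self.n_bins:
            raise ValueError(
                "trunk pooling must land on the bin resolution: "
                f"2^{self.trunk_blocks} != bin_width {self.bin_width}")

    @property
    def n_bins(self) -> int:
        return self.window_len // self.bin_width

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        stack = []
        for item in raw.pop("stack", []):
            item = dict(item)
            kind = item.pop("type").lower()
            repeat = int(item.pop("repeat", 1))
            spec_cls = {"mamba": MambaSpec, "hyena": HyenaSpec, "attn": AttnSpec}[kind]
            stack.extend(spec_cls(**item) for _ in range(repeat))
        return cls(stack=stack, **raw)


@dataclasses.dataclass
class TrainConfig:
    """Optimizer and schedule settings (reference defaults)."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    warmup_steps: int = 10_000
    clip_block: float = 5.0
    clip_global: float = 10.0
    batch_size: int = 2
    l2_coeff: float = 1e-6
    multinomial_weight: float = 4.0
    crop_bins: int = 2_048
    shift_max: int = 3
    augment: bool = True
    max_epochs: int = 1000
    max_steps: int | None = None
    patience: int = 5               # epochs without val improvement
    eval_every_steps: int | None = None

    def __post_init__(self):
        for f in ("lr", "beta1", "beta2", "clip_block", "clip_global",
                  "batch_size", "multinomial_weight"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def desk_model_config(n_tracks: int = 8) -> ModelConfig:
    """The desk-scale striped reference: 8,192-bp windows, d_model 64,
    [Mamba(N=8,E=1)×2 + UNet(attention+RoPE)]×2 on a five-block trunk.

    The trunk's early channels start at d_model/2 (rather than the
    full-scale geometric ramp from 4) so the first convolution has enough
    motif detectors at this small width.
    """
    return ModelConfig(
        n_tracks=n_tracks, d_model=64, window_len=8_192,
        trunk_channels=[32, 38, 46, 54, 64],
        stack=[MambaSpec(), MambaSpec(), AttnSpec(pos_mode="ROPE", d_qk=16)] * 2)


def desk_train_config(**overrides) -> TrainConfig:
    """Training settings scaled to the desk model: the reference schedule's
    10,000-step warm-up and 1e-4 rate are sized for multi-week runs on
    thousands of tracks; a small model on a small corpus wants a shorter
    warm-up and a larger step."""
    kw = dict(lr=2e-3, warmup_steps=100, crop_bins=32, max_steps=500,
              eval_every_steps=None, patience=100, max_epochs=10_000)
    kw.update(overrides)
    return TrainConfig(**kw)


# -------------------------------------------------------------------------
# the model

class Model(Module):
    """Trunk → residual layer stack → per-track affine + softplus head."""

    def __init__(self, rng: np.random.Generator, cfg: ModelConfig):
        self.cfg = cfg
        self.trunk = Trunk(rng, cfg.d_model, cfg.trunk_blocks,
                           cfg.trunk_first_width, cfg.trunk_width,
                           channels=cfg.trunk_channels)
        L_bins = cfg.n_bins
        self.layers: list[Module] = []
        for spec in cfg.stack:
            if isinstance(spec, MambaSpec):
                self.layers.append(MambaLayer(rng, SSMConfig(
                    d_model=cfg.d_model, N=spec.N, E=spec.E,
                    bidirectional=spec.bidirectional)))
            elif isinstance(spec, HyenaSpec):
                self.layers.append(HyenaLayer(rng, HyenaConfig(
                    d_model=cfg.d_model, order=spec.order,
                    channel_mixing=spec.channel_mixing,
                    siren_init=spec.siren_init), L_bins))
            elif isinstance(spec, AttnSpec):
                attn = AttentionLayer(rng, AttentionConfig(
                    d_model=cfg.d_model, heads=spec.heads, d_qk=spec.d_qk,
                    pos_mode=spec.pos_mode, chunk_len=spec.chunk_len))
                self.layers.append(
                    UNetWrap(rng, [attn], cfg.d_model, spec.unet_rounds)
                    if spec.unet_rounds > 0 else attn)
            else:
                raise ValueError(f"unknown layer spec {spec!r}")
        self.head = Linear(rng, cfg.d_model, cfg.n_tracks)

    def __call__(self, onehot) -> Tensor:
        x = ad.as_tensor(onehot)
        if x.shape != (self.cfg.window_len, 4):
            raise ValueError(
                f"expected input ({self.cfg.window_len}, 4), got {x.shape}")
        dtype = self.head.W.value.dtype
        if x.value.dtype != dtype:
            x = Tensor(x.value.astype(dtype))
        x = self.trunk(x)
        for layer in self.layers:
            x = layer(x)
        return softplus(self.head(x)) + self.cfg.rate_floor

    def predict(self, onehot: np.ndarray) -> np.ndarray:
        return self(Tensor(onehot)).value


def build_model(cfg: ModelConfig, seed: int) -> Model:
    """Deterministically initialised model (same seed → identical params)."""
    return Model(np.random.default_rng(seed), cfg)


# -------------------------------------------------------------------------
# loss

def poisson_multinomial_terms(pred_rates, counts, eps: float = 1e-9
                              ) -> tuple[Tensor, Tensor]:
    """The two loss components, summed over tracks: Poisson on totals
    (Λ − X·log Λ) and multinomial on the positional distribution
    (−Σ_i x_i log(λ_i/Λ))."""
    lam = ad.as_tensor(pred_rates)
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(lam.value <= 0):
        raise ValueError("predicted rates must be strictly positive")
    x = Tensor(counts.astype(lam.value.dtype))
    Lam = lam.sum(axis=0)                       # (T,)
    X = counts.sum(axis=0)
    poisson = (Lam - Tensor(X) * (Lam + eps).log()).sum()
    multinom = -(x * ((lam + eps).log() - (Lam + eps).log().reshape(1, -1))).sum()
    return poisson, multinom


def poisson_multinomial_loss(pred_rates, counts, w: float = 4.0,
                             eps: float = 1e-9):
    """Poisson(total) + w · multinomial(position distribution) per track.

    loss = Σ_tracks [Λ − X·log Λ] + w·[−Σ_i x_i log(λ_i/Λ)] with
    Λ = Σ_i λ_i and X = Σ_i x_i.  At w = 1 the gradient wrt the rates
    equals that of the independent per-bin Poisson likelihood
    Σ_i (λ_i − x_i log λ_i) exactly.
    """
    t = isinstance(pred_rates, Tensor)
    poisson, multinom = poisson_multinomial_terms(pred_rates, counts, eps)
    total = poisson + w * multinom
    return total if t else float(total.value)


# -------------------------------------------------------------------------
# equivariance diagnostics

def revcomp_tracks(pred: np.ndarray, meta: Sequence[TrackMeta]) -> np.ndarray:
    """The strand-exchange transform of a prediction: reverse the bins and
    exchange each forward/reverse track pair."""
    perm = _pair_permutation(meta)
    return pred[::-1][:, perm]


def equivariance_gap(model: Callable[[np.ndarray], np.ndarray],
                     onehot: np.ndarray, meta: Sequence[TrackMeta]) -> float:
    """Relative departure from reverse-complement equivariance:
    ‖f(revcomp(s)) − revcomp_tracks(f(s))‖ / ‖f(s)‖.

    The denominator averages the norms of both strand predictions, which
    makes the gap exactly invariant to which strand is called forward
    (the numerator already is, because the strand-exchange transform is a
    norm-preserving involution).  Usable (scaled by a small coefficient)
    as an additive training penalty.
    """
    f = np.asarray(model(onehot) if not hasattr(model, "predict")
                   else model.predict(onehot))
    f_rc = np.asarray(model(revcomp_onehot(onehot)) if not hasattr(model, "predict")
                      else model.predict(revcomp_onehot(onehot)))
    expected = revcomp_tracks(f, meta)
    denom = 0.5 * (np.linalg.norm(f) + np.linalg.norm(f_rc))
    return float(np.linalg.norm(f_rc - expected) / (denom + 1e-30))


def equivariance_penalty(model: Model, onehot: np.ndarray,
                         meta: Sequence[TrackMeta], coeff: float = 1e-2,
                         eps: float = 1e-30) -> Tensor:
    """Differentiable version of the equivariance gap, for use as a weak
    additive loss term: coeff · ‖f(revcomp s) − revcomp_tracks(f(s))‖² /
    (mean strand norm)².  Runs the model twice inside the tape, so its
    value equals coeff · equivariance_gap² and its gradient pulls the
    model toward strand-exchange equivariance.
    """
    perm = _pair_permutation(meta)
    f = model(onehot)
    f_rc = model(revcomp_onehot(np.asarray(onehot)))
    expected = f.flip(0)[:, perm]
    diff = f_rc - expected
    num = (diff * diff).sum()
    norm_f = (f * f).sum().sqrt()
    norm_rc = (f_rc * f_rc).sum().sqrt()
    den = (0.5 * (norm_f + norm_rc)) ** 2.0
    return coeff * (num / (den + eps))


# -------------------------------------------------------------------------
# optimisation

def lr_schedule(step: int, cfg: TrainConfig) -> float:
    """Linear warm-up to cfg.lr over cfg.warmup_steps, constant after."""
    if step < 0:
        raise ValueError("step must be nonnegative")
    return cfg.lr * min(1.0, step / cfg.warmup_steps)


_BLOCK_RE = re.compile(r"^(.*?\.\d+)\.|^([^.]+)\.")


def _block_key(name: str) -> str:
    """The clipping block of a parameter: the named layer group it lives
    in (e.g. ``trunk.blocks.0``, ``layers.3``, ``head``)."""
    parts = name.split(".")
    for i, p in enumerate(parts):
        if p.isdigit():
            return ".".join(parts[:i + 1])
    return parts[0]


def clip_gradients(grads: dict[str, np.ndarray], cfg: TrainConfig
                   ) -> dict[str, np.ndarray]:
    """Two-stage norm clipping: each block to ≤ clip_block, then the
    global norm to ≤ clip_global.  Idempotent on compliant gradients."""
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {name}")
    out = dict(grads)
    blocks: dict[str, list[str]] = {}
    for name in out:
        blocks.setdefault(_block_key(name), []).append(name)
    for names in blocks.values():
        norm = np.sqrt(sum(float(np.sum(out[n] ** 2)) for n in names))
        if norm > cfg.clip_block:
            scale = cfg.clip_block / norm
            for n in names:
                out[n] = out[n] * scale
    gnorm = np.sqrt(sum(float(np.sum(g ** 2)) for g in out.values()))
    if gnorm > cfg.clip_global:
        scale = cfg.clip_global / gnorm
        out = {n: g * scale for n, g in out.items()}
    return out


class Adam:
    """Plain Adam with bias correction."""

    def __init__(self, params: dict[str, Tensor], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def step(self, params: dict[str, Tensor], grads: dict[str, np.ndarray],
             lr: float, eps: float = 1e-8) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1 ** self.t
        b2t = 1.0 - c.beta2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            p.value -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + eps)


# -------------------------------------------------------------------------
# training loop

@dataclasses.dataclass
class TrainResult:
    history: list[dict]            # per-logged-step records
    epoch_val_r: list[float]       # mean Pearson r on validation per epoch
    best_val_r: float
    best_params: dict[str, np.ndarray]
    steps: int


def _mean_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean over tracks of Pearson r between concatenated bins."""
    rs = []
    for t in range(pred.shape[1]):
        p, o = pred[:, t], obs[:, t]
        if o.std() == 0 or p.std() == 0:
            continue
        rs.append(float(np.corrcoef(p, o)[0, 1]))
    return float(np.mean(rs)) if rs else float("nan")


def train(model: Model,
          windows: Sequence[SequenceWindow],
          targets: Sequence[np.ndarray],
          meta: Sequence[TrackMeta],
          train_idx: Sequence[int],
          val_idx: Sequence[int],
          cfg: TrainConfig,
          seed: int,
          log_every: int = 50) -> TrainResult:
    """Train with shuffled epochs, batch accumulation, both augmentations,
    L2 regularisation, two-stage gradient clipping, linear warm-up Adam,
    and early stopping on validation mean Pearson r.

    ``targets`` are squashed binned coverage matrices (n_bins, T); the
    loss is evaluated on the interior after cropping ``cfg.crop_bins``
    bins from each end.  Deterministic given ``seed``.
    """
    train_idx = list(train_idx)
    if not train_idx:
        raise ValueError("empty training set")
    if set(train_idx) & set(val_idx):
        raise ValueError("train and validation windows must be disjoint")
    rng = np.random.default_rng(seed)
    params = model.parameters()
    opt = Adam(params, cfg)
    crop = cfg.crop_bins
    n_bins = model.cfg.n_bins
    if 2 * crop >= n_bins:
        raise ValueError("crop_bins too large for the model's output")
    perm_tracks = _pair_permutation(meta)

    def eval_val() -> float:
        preds, obs = [], []
        for i in val_idx:
            p = model.predict(windows[i].onehot)[crop:n_bins - crop]
            preds.append(p)
            obs.append(targets[i][crop:n_bins - crop])
        if not preds:
            return float("nan")
        return _mean_pearson(np.concatenate(preds), np.concatenate(obs))

    history: list[dict] = []
    epoch_val_r: list[float] = []
    best_val = -np.inf
    best_params = {k: p.value.copy() for k, p in params.items()}
    bad_epochs = 0
    step = 0
    done = False

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_idx))
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_idx[j] for j in order[lo:lo + cfg.batch_size]]
            model.zero_grad()
            batch_losses = []
            for i in batch:
                oh = windows[i].onehot
                tgt = targets[i]
                if cfg.augment:
                    shift = int(rng.integers(-cfg.shift_max, cfg.shift_max + 1))
                    if shift > 0:
                        sh = np.zeros_like(oh)
                        sh[shift:] = oh[:-shift]
                        oh = sh
                    elif shift < 0:
                        sh = np.zeros_like(oh)
                        sh[:shift] = oh[-shift:]
                        oh = sh
                    if rng.random() < 0.5:
                        oh = revcomp_onehot(oh)
                        tgt = tgt[::-1][:, perm_tracks]
                pred = model(Tensor(oh))
                pois, mult = poisson_multinomial_terms(
                    pred[crop:n_bins - crop], tgt[crop:n_bins - crop])
                loss = pois + cfg.multinomial_weight * mult
                if cfg.l2_coeff > 0:
                    l2 = None
                    for p in params.values():
                        term = (p * p).sum()
                        l2 = term if l2 is None else l2 + term
                    loss = loss + cfg.l2_coeff * l2
                scaled = loss * (1.0 / len(batch))
                scaled.backward()
                batch_losses.append((float(loss.value), float(pois.value),
                                     float(mult.value)))
            grads = {k: p.grad for k, p in params.items() if p.grad is not None}
            grads = clip_gradients(grads, cfg)
            lr = lr_schedule(step, cfg)
            opt.step({k: params[k] for k in grads}, grads, lr)
            step += 1
            if step % log_every == 0 or step == 1:
                tot, pois_m, mult_m = np.mean(batch_losses, axis=0)
                history.append({"step": step, "epoch": epoch, "lr": lr,
                                "loss": float(tot), "poisson": float(pois_m),
                                "multinomial": float(mult_m)})
            if cfg.eval_every_steps and step % cfg.eval_every_steps == 0:
                r = eval_val()
                history.append({"step": step, "epoch": epoch, "lr": lr,
                                "val_r": r})
                if r > best_val:
                    best_val = r
                    best_params = {k: p.value.copy() for k, p in params.items()}
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        val_r = eval_val()
        epoch_val_r.append(val_r)
        if val_r > best_val:
            best_val = val_r
            best_params = {k: p.value.copy() for k, p in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
        if done or bad_epochs >= cfg.patience:
            break
    return TrainResult(history, epoch_val_r, float(best_val), best_params, step)


def load_params(model: Model, params: dict[str, np.ndarray]) -> None:
    for k, p in model.parameters().items():
        p.value[...] = params[k]
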