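"""Convolutional trunk blocks, dilated-kernel composition, SIREN implicit
long-convolution filters, FFT long convolution, and the bidirectional
gated long-convolution (Hyena-style) layer.

The trunk is the standard front end of sequence-to-coverage models: five
(or more) rounds of norm → activation → convolution → twofold max-pool,
taking a one-hot (L, 4) input to a (L/2^rounds, d_model) embedding — at
the reference scale, (393216, 4) → (12288, 768) over 32-bp bins.

The long-convolution layer generates its length-L kernel implicitly with
a SIREN (a coordinate MLP with sinusoidal activations).  When such a
kernel is drawn with the conventional unit-variance final layer, the
convolution output has variance proportional to L and deep stacks
explode; the final layer here is therefore initialised so its variance
scales as 1/L, which keeps activations bounded at depth (both behaviours
are available, for the regression test that documents the pathology).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, gelu, long_conv, silu, softplus
from .nn import ChannelNorm, LayerNorm, Linear, Module, Param, conv1d, \
    depthwise_conv1d, lecun_normal, maxpool2

__all__ = ["ConvBlockConfig", "ConvBlock", "Trunk", "trunk_channel_schedule",
           "compose_dilated_kernels", "SirenFilter", "fft_long_conv",
           "HyenaConfig", "HyenaLayer"]


# -------------------------------------------------------------------------
# trunk

@dataclasses.dataclass
class ConvBlockConfig:
    in_channels: int
    out_channels: int
    kernel_width: int = 5
    pool: int = 2


class ConvBlock(Module):
    """norm → GeLU → same-padded conv → twofold max-pool (in that order)."""

    def __init__(self, rng: np.random.Generator, cfg: ConvBlockConfig):
        if cfg.pool != 2:
            raise ValueError("trunk blocks use twofold pooling")
        self.cfg = cfg
        self.norm = ChannelNorm(cfg.in_channels)
        self.W = Param(lecun_normal(
            rng, (cfg.kernel_width, cfg.in_channels, cfg.out_channels)))
        self.b = Param(np.zeros(cfg.out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[0] % 2 != 0:
            raise ValueError(f"conv block needs even length, got {x.shape[0]}")
        return maxpool2(conv1d(gelu(self.norm(x)), self.W, self.b))


def trunk_channel_schedule(d_model: int, n_blocks: int, c_in: int = 4) -> list[int]:
    """Geometric interpolation of channel counts from the input width to
    d_model over the trunk blocks."""
    return [int(round(c_in * (d_model / c_in) ** (i / n_blocks)))
            for i in range(1, n_blocks + 1)]


class Trunk(Module):
    """The initial conv/pool stack: (L, 4) → (L / 2^n_blocks, d_model)."""

    def __init__(self, rng: np.random.Generator, d_model: int, n_blocks: int = 5,
                 first_width: int = 15, width: int = 5,
                 channels: Sequence[int] | None = None):
        if channels is not None:
            if len(channels) != n_blocks or channels[-1] != d_model:
                raise ValueError("channels must list one width per block, "
                                 "ending at d_model")
            chans = [4] + list(channels)
        else:
            chans = [4] + trunk_channel_schedule(d_model, n_blocks)
        self.blocks = [
            ConvBlock(rng, ConvBlockConfig(chans[i], chans[i + 1],
                                           first_width if i == 0 else width))
            for i in range(n_blocks)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return x


# -------------------------------------------------------------------------
# dilated-kernel composition

def _dilate(kernel: np.ndarray, d: int) -> np.ndarray:
    if d == 1:
        return kernel
    out = np.zeros(d * (kernel.size - 1) + 1, dtype=kernel.dtype)
    out[::d] = kernel
    return out


def compose_dilated_kernels(kernels: Sequence[np.ndarray],
                            dilations: Sequence[int]) -> np.ndarray:
    """Collapse serial single-channel dilated convolutions into one kernel.

    The space of 1-D convolutions is closed under composition and
    dilation, so applying kernels k_i with dilations d_i in series equals
    one convolution with the composed kernel (support width
    1 + Σ d_i(w_i − 1)).  Only depthwise (single-channel) kernels compose
    this way; channel-mixing kernels are rejected.
    """
    if len(kernels) != len(dilations):
        raise ValueError("one dilation per kernel required")
    out = np.ones(1)
    for k, d in zip(kernels, dilations):
        k = np.asarray(k, dtype=np.float64)
        if k.ndim != 1:
            raise ValueError("compose_dilated_kernels takes single-channel "
                             "(1-D) kernels; channel mixing does not compose")
        if d < 1:
            raise ValueError("dilation must be >= 1")
        out = np.convolve(out, _dilate(k, d))
    return out


# -------------------------------------------------------------------------
# SIREN implicit filters

class SirenFilter(Module):
    """Coordinate network t ∈ [0,1) → per-channel kernel value.

    Two sin-activated hidden layers of the given width with frequency
    scale ω; the final linear layer's initial variance carries the kernel
    scale rule: ``init="inv_length"`` targets Var(kernel) ≈ c/L,
    ``init="unit"`` the conventional unit-variance SIREN output.
    """

    def __init__(self, rng: np.random.Generator, d_model: int, hidden: int = 32,
                 n_hidden: int = 2, omega: float = 30.0,
                 init: str = "inv_length", length_scale: int | None = None):
        if init not in ("inv_length", "unit"):
            raise ValueError(f"unknown init mode {init!r}")
        self.omega = omega
        # first layer: U(-1,1) on the single coordinate input
        self.W0 = Param(rng.uniform(-1, 1, (1, hidden)))
        self.b0 = Param(rng.uniform(-1, 1, hidden))
        bound = np.sqrt(6.0 / hidden) / omega
        self.Ws = [Param(rng.uniform(-bound, bound, (hidden, hidden)))
                   for _ in range(n_hidden - 1)]
        self.bs = [Param(rng.uniform(-1, 1, hidden) * 0.0)
                   for _ in range(n_hidden - 1)]
        var = 2.0 / hidden
        if init == "inv_length":
            if length_scale is None:
                raise ValueError("inv_length init needs the kernel length")
            var = var / length_scale
        self.W_out = Param(rng.normal(0.0, np.sqrt(var), (hidden, d_model)))
        self.b_out = Param(np.zeros(d_model))

    def __call__(self, L: int) -> Tensor:
        t = Tensor(np.linspace(0.0, 1.0, L, endpoint=False)[:, None])
        h = ((t @ self.W0 + self.b0) * self.omega).sin()
        for W, b in zip(self.Ws, self.bs):
            h = ((h @ W + b) * self.omega).sin()
        k = h @ self.W_out + self.b_out
        if not np.all(np.isfinite(k.value)):
            raise FloatingPointError("non-finite SIREN kernel")
        return k


def fft_long_conv(x, kernel, causal: bool = False):
    """Per-channel linear convolution with a kernel as long as the input.

    FFT-based at length 2L so the convolution is linear, not circular.
    causal=True aligns kernel index 0 with lag 0 (output sees only the
    past); causal=False centres the kernel (index L//2 at lag 0) so both
    flanks contribute.  Accepts Tensors (differentiable) or ndarrays.
    """
    t = isinstance(x, Tensor) or isinstance(kernel, Tensor)
    xt, kt = ad.as_tensor(x), ad.as_tensor(kernel)
    y = long_conv(xt, kt, causal=causal)
    return y if t else y.value


# -------------------------------------------------------------------------
# Hyena-style gated long-convolution layer

@dataclasses.dataclass
class HyenaConfig:
    d_model: int
    order: int = 2                  # number of gating recurrences
    short_width: int = 3            # inner nearest-neighbour conv width
    channel_mixing: bool = False    # dense (mixing) short convs instead of depthwise
    siren_hidden: int = 32
    siren_omega: float = 30.0
    siren_init: str = "inv_length"
    causal: bool = False

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")


class HyenaLayer(Module):
    """LayerNorm → (order+1) projected branches with short nearest-neighbour
    convs → iterated elementwise gating interleaved with FFT long
    convolutions under implicit SIREN kernels → output projection →
    residual.  SiLU activations throughout; kernels are windowed by a
    learnable per-channel exponential-decay envelope.
    """

    def __init__(self, rng: np.random.Generator, cfg: HyenaConfig, L: int):
        d = cfg.d_model
        self.cfg = cfg
        self.L = L
        self.norm = LayerNorm(d)
        self.proj = Linear(rng, d, (cfg.order + 1) * d)
        if cfg.channel_mixing:
            self.short_w = [Param(lecun_normal(rng, (cfg.short_width, d, d)))
                            for _ in range(cfg.order + 1)]
        else:
            self.short_w = [Param(lecun_normal(rng, (cfg.short_width, d),
                                               fan_in=cfg.short_width))
                            for _ in range(cfg.order + 1)]
        self.filters = [SirenFilter(rng, d, hidden=cfg.siren_hidden,
                                    omega=cfg.siren_omega, init=cfg.siren_init,
                                    length_scale=L)
                        for _ in range(cfg.order)]
        # softplus(decay_raw) is the per-channel envelope rate
        self.decay_raw = [Param(np.full(d, 0.0)) for _ in range(cfg.order)]
        self.out_proj = Linear(rng, d, d)

    def kernel(self, i: int, L: int) -> Tensor:
        """The i-th long-conv kernel: SIREN output × exponential envelope."""
        k = self.filters[i](L)
        pos = np.arange(L, dtype=np.float64)
        center = 0.0 if self.cfg.causal else L // 2
        dist = Tensor((np.abs(pos - center) / L)[:, None])
        env = (-(softplus(self.decay_raw[i]) * dist)).exp()
        return k * env

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        L, d = x.shape
        z = self.norm(x)
        branches = []
        p = self.proj(z)
        for i in range(cfg.order + 1):
            b = p[:, i * d:(i + 1) * d]
            if cfg.channel_mixing:
                b = conv1d(b, self.short_w[i])
            else:
                b = depthwise_conv1d(b, self.short_w[i])
            branches.append(silu(b))
        v = branches[0]
        for i in range(cfg.order):
            v = branches[i + 1] * fft_long_conv(v, self.kernel(i, L),
                                                causal=cfg.causal)
        return x + self.out_proj(v)
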