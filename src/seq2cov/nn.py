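"""Shared neural-net plumbing: parameter modules, norms, convolutions.

Layers operate on single sequences shaped (L, C); batching is done by the
training loop (batch size 2 in the reference schedule), so there is no
batch axis.  The "batch" normalisation used with the convolutional trunk
therefore computes its statistics per channel over the length axis of the
example being processed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Param", "Linear", "RMSNorm", "LayerNorm", "ChannelNorm",
           "conv1d", "depthwise_conv1d", "maxpool2", "lecun_normal"]


def lecun_normal(rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int | None = None) -> np.ndarray:
    if fan_in is None:
        fan_in = shape[0] if len(shape) < 3 else shape[0] * shape[1]
    return rng.normal(0.0, 1.0 / np.sqrt(max(fan_in, 1)), shape)


def Param(value: np.ndarray) -> Tensor:
    return Tensor(np.asarray(value, dtype=np.float64), requires_grad=True)


class Module:
    """Base class: recursively collects Tensor parameters from attributes."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor) and attr.requires_grad:
                out[key] = attr
            elif isinstance(attr, Module):
                out.update(attr.parameters(f"{key}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.update(item.parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def n_params(self) -> int:
        return sum(p.value.size for p in self.parameters().values())

    def astype(self, dtype) -> "Module":
        """Cast all parameters in place (float32 halves training cost)."""
        for p in self.parameters().values():
            p.value = p.value.astype(dtype)
        return self


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True, scale: float = 1.0):
        self.W = Param(scale * lecun_normal(rng, (d_in, d_out)))
        self.b = Param(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class RMSNorm(Module):
    def __init__(self, d: int, eps: float = 1e-6):
        self.g = Param(np.ones(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        ms = (x * x).mean(axis=-1, keepdims=True)
        return x / (ms + self.eps).sqrt() * self.g


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-6):
        self.g = Param(np.ones(d))
        self.b = Param(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class ChannelNorm(Module):
    """Per-channel normalisation over the length axis (the per-example
    stand-in for batch statistics in the conv trunk)."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Param(np.ones(d))
        self.b = Param(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=0, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


def conv1d(x: Tensor, W: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded dense 1-D convolution.

    x: (L, C_in); W: (K, C_in, C_out) -> (L, C_out).
    """
    from .autodiff import conv1d_dense

    return conv1d_dense(x, W, bias)


def depthwise_conv1d(x: Tensor, W: Tensor, causal: bool = False) -> Tensor:
    """Per-channel short convolution.  x: (L, C); W: (K, C)."""
    from .autodiff import conv1d_depthwise

    return conv1d_depthwise(x, W, causal)


def maxpool2(x: Tensor) -> Tensor:
    """Twofold max-pooling along the length axis."""
    L, C = x.shape
    if L % 2 != 0:
        raise ValueError(f"maxpool2 requires even length, got {L}")
    return x.reshape(L // 2, 2, C).max(axis=1)
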