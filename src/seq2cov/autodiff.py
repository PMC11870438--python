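"""Minimal reverse-mode automatic differentiation over numpy arrays.

The differentiable layers in this package (selective-SSM scans, gated long
convolutions, attention) are built on this tape: a :class:`Tensor` wraps an
ndarray, records its parents and a backward closure, and ``backward()``
walks the graph in reverse topological order.  Two operations get custom
vector-Jacobian products because composing them from primitives would be
wasteful: the first-order linear recurrence (``linear_scan``) whose adjoint
is itself a reverse-time linear recurrence, and FFT-based long convolution
(``long_conv``) whose adjoint is a pair of correlations.

Design choices: float64 by default for well-conditioned gradient checks
(callers can pass float32 arrays and everything stays float32); gradients
accumulate by summation; broadcasting is handled by summing the gradient
back to the parent's shape.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy import fft as sfft
from scipy import special as ssp

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gelu",
    "linear_scan",
    "linear_scan_numpy",
    "long_conv",
    "long_conv_numpy",
    "relu",
    "sigmoid",
    "silu",
    "softplus",
    "stop_gradient",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` down to ``shape``."""
    if grad.shape == shape:
        return grad
    # Sum over leading broadcast axes.
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # Sum over axes that were 1 in the original shape.
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph.

    Parameters
    ----------
    value : array-like
        The forward value.
    requires_grad : bool
        Whether gradients should flow to this node.  Leaf parameters set
        this; interior nodes inherit it from their parents.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _make(value: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(value)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        # gradients are only ever rebound (never mutated in place), so the
        # incoming array can be aliased safely
        g = _sum_to_shape(np.asarray(g), self.value.shape)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, grad={self.requires_grad})"

    # -- backward pass ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node.  ``grad`` defaults to ones."""
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_val = self.value + other.value

        def back(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(out_val, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accum(-g)

        return Tensor._make(-self.value, (self,), back)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_val = self.value * other.value

        def back(g):
            if self.requires_grad:
                self._accum(g * other.value)
            if other.requires_grad:
                other._accum(g * self.value)

        return Tensor._make(out_val, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_val = self.value / other.value

        def back(g):
            if self.requires_grad:
                self._accum(g / other.value)
            if other.requires_grad:
                other._accum(-g * self.value / (other.value ** 2))

        return Tensor._make(out_val, (self, other), back)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_val = self.value ** p

        def back(g):
            self._accum(g * p * self.value ** (p - 1))

        return Tensor._make(out_val, (self,), back)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_val = self.value @ other.value

        def back(g):
            a, b = self.value, other.value
            if self.requires_grad:
                self._accum(g @ np.swapaxes(b, -1, -2))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accum(gb)

        return Tensor._make(out_val, (self, other), back)

    def __getitem__(self, idx):
        out_val = self.value[idx]
        basic = isinstance(idx, (slice, int)) or (
            isinstance(idx, tuple) and all(isinstance(i, (slice, int)) for i in idx))

        def back(g):
            full = np.zeros_like(self.value)
            if basic:
                full[idx] = g     # basic indexing never repeats positions
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_val, (self,), back)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.value.shape
        out_val = self.value.reshape(shape)

        def back(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_val, (self,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.value.ndim)))
        inv = tuple(np.argsort(axes))
        out_val = self.value.transpose(axes)

        def back(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_val, (self,), back)

    def flip(self, axis: int = 0):
        out_val = np.flip(self.value, axis=axis)

        def back(g):
            self._accum(np.flip(g, axis=axis))

        return Tensor._make(out_val, (self,), back)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` in np.pad format."""
        out_val = np.pad(self.value, pad_width)
        slices = tuple(slice(b, b + n) for (b, _), n in zip(pad_width, self.value.shape))

        def back(g):
            self._accum(g[slices])

        return Tensor._make(out_val, (self,), back)

    def repeat(self, reps: int, axis: int):
        """Nearest-neighbour upsampling along ``axis``."""
        out_val = np.repeat(self.value, reps, axis=axis)
        n = self.value.shape[axis]

        def back(g):
            shp = list(g.shape)
            shp[axis:axis + 1] = [n, reps]
            self._accum(g.reshape(shp).sum(axis=axis + 1))

        return Tensor._make(out_val, (self,), back)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_val = self.value.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.value.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape))

        return Tensor._make(out_val, (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max reduction; ties send the full gradient to the first argmax."""
        out_val = self.value.max(axis=axis, keepdims=keepdims)
        arg = self.value.argmax(axis=axis)

        def back(g):
            if not keepdims:
                gg = np.expand_dims(g, axis)
            else:
                gg = g
            full = np.zeros_like(self.value)
            np.put_along_axis(full, np.expand_dims(arg, axis), gg, axis=axis)
            self._accum(full)

        return Tensor._make(out_val, (self,), back)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_val = np.exp(self.value)

        def back(g):
            self._accum(g * out_val)

        return Tensor._make(out_val, (self,), back)

    def log(self):
        out_val = np.log(self.value)

        def back(g):
            self._accum(g / self.value)

        return Tensor._make(out_val, (self,), back)

    def sqrt(self):
        out_val = np.sqrt(self.value)

        def back(g):
            self._accum(g * 0.5 / out_val)

        return Tensor._make(out_val, (self,), back)

    def sin(self):
        out_val = np.sin(self.value)

        def back(g):
            self._accum(g * np.cos(self.value))

        return Tensor._make(out_val, (self,), back)

    def tanh(self):
        out_val = np.tanh(self.value)

        def back(g):
            self._accum(g * (1.0 - out_val ** 2))

        return Tensor._make(out_val, (self,), back)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stop_gradient(x: Tensor) -> Tensor:
    return Tensor(np.asarray(x.value))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_val, tensors, back)


# -- activations ----------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    out_val = ssp.expit(x.value)

    def back(g):
        x._accum(g * out_val * (1.0 - out_val))

    return Tensor._make(out_val, (x,), back)


def softplus(x: Tensor) -> Tensor:
    out_val = np.logaddexp(0.0, x.value)

    def back(g):
        x._accum(g * ssp.expit(x.value))

    return Tensor._make(out_val, (x,), back)


_SQRT_2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-form) GeLU."""
    v = x.value
    cdf = 0.5 * (1.0 + ssp.erf(v / _SQRT_2))
    out_val = v * cdf

    def back(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * v * v)
        x._accum(g * (cdf + v * pdf))

    return Tensor._make(out_val, (x,), back)


def silu(x: Tensor) -> Tensor:
    s = ssp.expit(x.value)
    out_val = x.value * s

    def back(g):
        x._accum(g * (s + x.value * s * (1.0 - s)))

    return Tensor._make(out_val, (x,), back)


def relu(x: Tensor) -> Tensor:
    mask = x.value > 0

    def back(g):
        x._accum(g * mask)

    return Tensor._make(np.where(mask, x.value, 0.0), (x,), back)


# -- linear recurrence (selective-scan workhorse) --------------------------

def linear_scan_numpy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Inclusive scan of ``h_t = a_t * h_{t-1} + b_t`` (h_0 = 0) along axis 0.

    Parallel prefix by recursive doubling over the associative combine
    ``(a1, b1) ∘ (a2, b2) = (a1*a2, a2*b1 + b2)``.  log2(L) vectorised
    passes; identical values to the sequential recurrence up to fp error.
    """
    a = a.copy()
    h = b.copy()
    L = a.shape[0]
    d = 1
    while d < L:
        # combine element i-d (earlier) into element i
        h[d:] = h[d:] + a[d:] * h[:-d]
        a[d:] = a[d:] * a[:-d]
        d *= 2
    return h


def linear_scan_sequential_numpy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Reference sequential evaluation of the same recurrence (the oracle)."""
    h = np.zeros_like(b)
    prev = np.zeros_like(b[0])
    for t in range(a.shape[0]):
        prev = a[t] * prev + b[t]
        h[t] = prev
    return h


def linear_scan(a: Tensor, b: Tensor, checkpoint_every: int | None = None) -> Tensor:
    """Differentiable inclusive first-order linear recurrence along axis 0.

    The adjoint is itself a reverse-time linear recurrence:
    with ``gh`` the gradient wrt h, ``gb_t = gh_t + a_{t+1} gb_{t+1}`` and
    ``ga_t = gb_t * h_{t-1}``.  ``checkpoint_every`` chunks the forward pass
    (recompute-in-backward granularity); values are unchanged.
    """
    a_val, b_val = a.value, b.value
    if checkpoint_every is None or checkpoint_every >= a_val.shape[0]:
        h = linear_scan_numpy(a_val, b_val)
    else:
        # blocked scan: scan each chunk, then carry the running state across
        h = np.empty_like(b_val)
        carry = np.zeros_like(b_val[0])
        for lo in range(0, a_val.shape[0], checkpoint_every):
            hi = min(lo + checkpoint_every, a_val.shape[0])
            blk = linear_scan_numpy(a_val[lo:hi], b_val[lo:hi])
            # fold the carry through the chunk: h_t += (prod a_{lo..t}) * carry
            amul = np.cumprod(a_val[lo:hi], axis=0)
            blk = blk + amul * carry
            h[lo:hi] = blk
            carry = blk[-1]

    def back(g):
        # reverse recurrence for gb
        a_rev = np.flip(a_val, axis=0)
        g_rev = np.flip(g, axis=0)
        # gb_rev_t = g_rev_t + a_rev_{t-1} * gb_rev_{t-1}; use scan with
        # shifted decay: decay_0 = 1 (no predecessor), decay_t = a_rev_{t-1}
        decay = np.concatenate([np.ones_like(a_rev[:1]), a_rev[:-1]], axis=0)
        gb = np.flip(linear_scan_numpy(decay, g_rev), axis=0)
        if b.requires_grad:
            b._accum(gb)
        if a.requires_grad:
            h_prev = np.concatenate([np.zeros_like(h[:1]), h[:-1]], axis=0)
            a._accum(gb * h_prev)

    return Tensor._make(h, (a, b), back)


# -- short convolutions (single fused primitives) --------------------------

def conv1d_dense(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded dense 1-D convolution as one tape node.

    x (L, C_in), W (K, C_in, C_out) -> (L, C_out).  Forward is an im2col
    tensordot; the adjoint scatters per-tap slices back into the padded
    input (K is small).
    """
    K = W.value.shape[0]
    L = x.value.shape[0]
    left = (K - 1) // 2
    right = K - 1 - left
    xp = np.pad(x.value, ((left, right), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=0)  # (L, Cin, K)
    y = np.einsum("lck,kco->lo", cols, W.value, optimize=True)
    if b is not None:
        y = y + b.value

    def back(g):
        if W.requires_grad:
            W._accum(np.einsum("lck,lo->kco", cols, g, optimize=True))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(K):
                gxp[j:j + L] += g @ W.value[j].T
            x._accum(gxp[left:left + L])
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=0))

    parents = (x, W) if b is None else (x, W, b)
    return Tensor._make(y, parents, back)


def conv1d_depthwise(x: Tensor, W: Tensor, causal: bool = False) -> Tensor:
    """Per-channel short convolution as one tape node.

    x (L, C), W (K, C) -> (L, C); causal pads only on the left.
    """
    K = W.value.shape[0]
    L = x.value.shape[0]
    left = K - 1 if causal else (K - 1) // 2
    right = K - 1 - left
    xp = np.pad(x.value, ((left, right), (0, 0)))
    y = np.zeros_like(x.value)
    for j in range(K):
        y += xp[j:j + L] * W.value[j]

    def back(g):
        if W.requires_grad:
            gW = np.empty_like(W.value)
            for j in range(K):
                gW[j] = (xp[j:j + L] * g).sum(axis=0)
            W._accum(gW)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(K):
                gxp[j:j + L] += g * W.value[j]
            x._accum(gxp[left:left + L])

    return Tensor._make(y, (x, W), back)


# -- FFT long convolution --------------------------------------------------

def _lin_conv_fft(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Full linear convolution along axis 0 of two (L, C) arrays -> (2L-1, C)."""
    n = x.shape[0] + k.shape[0] - 1
    nfft = sfft.next_fast_len(n, real=True)
    X = np.fft.rfft(x, nfft, axis=0)
    K = np.fft.rfft(k, nfft, axis=0)
    y = np.fft.irfft(X * K, nfft, axis=0)[:n]
    return y


def long_conv_numpy(x: np.ndarray, k: np.ndarray, causal: bool) -> np.ndarray:
    """Per-channel linear (non-circular) convolution of (L, C) with (L, C).

    causal=True: ``y_t = sum_{j<=t} k_j x_{t-j}`` — output sees only the past.
    causal=False: kernel index L//2 is aligned to lag 0 so both flanks
    contribute (``y_t = sum_j k_j x_{t-j+L//2}``).
    """
    L = x.shape[0]
    full = _lin_conv_fft(x, k)
    off = 0 if causal else k.shape[0] // 2
    return full[off:off + L]


def long_conv(x: Tensor, k: Tensor, causal: bool = False) -> Tensor:
    """Differentiable FFT long convolution (see :func:`long_conv_numpy`).

    Adjoints: dx = corr(dy, k), dk = corr(dy, x), both evaluated as linear
    convolutions with a flipped operand at the matching offset.
    """
    if x.value.shape != k.value.shape:
        raise ValueError(
            f"long_conv requires kernel length == sequence length, got "
            f"{k.value.shape} vs {x.value.shape}")
    L = x.value.shape[0]
    off = 0 if causal else L // 2
    y = long_conv_numpy(x.value, k.value, causal)

    def back(g):
        # y_t = sum_j k_j x_{t-j+off}
        # dx_s = sum_t g_t k_{t-s+off} = full(g, flip(k))[L-1-off+s]
        # dk_j = sum_t g_t x_{t-j+off} = full(g, flip(x))[L-1-off+j]
        if x.requires_grad:
            fc = _lin_conv_fft(g, np.flip(k.value, axis=0))
            x._accum(fc[L - 1 - off:2 * L - 1 - off])
        if k.requires_grad:
            fc = _lin_conv_fft(g, np.flip(x.value, axis=0))
            k._accum(fc[L - 1 - off:2 * L - 1 - off])

    return Tensor._make(y, (x, k), back)
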