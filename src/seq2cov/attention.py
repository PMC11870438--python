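"""Multi-head attention with three positional-encoding modes, chunked
(memory-tiled) attention numerically equal to dense attention, and the
U-Net pool/upsample wrapper that lets attention run at coarse resolution.

Positional modes: NONE (permutation-equivariant), ROPE (rotary embedding
of queries and keys, so scores depend only on the relative offset), and
ENFORMER_REL (additive logits from geometrically-spaced threshold
indicator features of the key−query separation).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, gelu, stop_gradient
from .nn import LayerNorm, Linear, Module, Param, lecun_normal, maxpool2

__all__ = ["AttentionConfig", "rope_encode", "enformer_rel_basis",
           "dense_attention", "chunked_attention", "AttentionLayer",
           "UNetWrap"]


@dataclasses.dataclass
class AttentionConfig:
    d_model: int
    heads: int = 4
    d_qk: int = 64
    pos_mode: str = "NONE"          # NONE | ROPE | ENFORMER_REL
    chunk_len: int | None = None
    basis_size: int = 32            # ENFORMER_REL feature count (symmetric+signed)
    ff_expansion: int = 2
    rope_base: float = 10_000.0

    def __post_init__(self):
        if self.pos_mode not in ("NONE", "ROPE", "ENFORMER_REL"):
            raise ValueError(f"unknown pos_mode {self.pos_mode!r}")
        if self.d_model % self.heads != 0:
            raise ValueError("d_model must be divisible by heads")

    @property
    def d_v(self) -> int:
        return self.d_model // self.heads


# -------------------------------------------------------------------------
# positional encodings

def rope_encode(x, positions=None, base: float = 10_000.0):
    """Rotary positional embedding of (L, d) queries or keys (d even).

    Each feature pair (2i, 2i+1) is rotated by θ_i·t with θ_i =
    base^(−2i/d); inner products of encoded vectors then depend only on
    the relative offset t−s.  Accepts Tensor or ndarray.
    """
    t = isinstance(x, Tensor)
    xt = ad.as_tensor(x)
    L, d = xt.shape
    if d % 2 != 0:
        raise ValueError("RoPE requires an even feature dimension")
    if positions is None:
        positions = np.arange(L)
    positions = np.asarray(positions, dtype=np.float64)
    theta = base ** (-np.arange(0, d, 2) / d)
    ang = positions[:, None] * theta[None, :]        # (L, d/2)
    cos = np.cos(ang).astype(xt.value.dtype)
    sin = np.sin(ang).astype(xt.value.dtype)
    even = xt[:, 0::2]
    odd = xt[:, 1::2]
    re = even * cos - odd * sin
    im = even * sin + odd * cos
    # interleave back
    out = concat([re.reshape(L, d // 2, 1), im.reshape(L, d // 2, 1)], axis=2)
    out = out.reshape(L, d)
    return out if t else out.value


def enformer_rel_basis(offsets: np.ndarray, n_basis: int = 32,
                       max_offset: int | None = None) -> np.ndarray:
    """Threshold-indicator features of relative separation.

    Half the features are symmetric (|offset| ≥ threshold), half signed
    (sign(offset)·indicator), with thresholds 0, 1, 2, 4, … geometrically
    spaced.  Offset 0 activates only the smallest (zero) threshold, and
    each feature, once switched on, stays on as |offset| grows.
    """
    offsets = np.asarray(offsets)
    half = n_basis // 2
    thresholds = np.concatenate([[0], 2 ** np.arange(half - 1)])
    if max_offset is not None:
        thresholds = np.minimum(thresholds, max_offset)
    ind = (np.abs(offsets)[..., None] >= thresholds).astype(np.float64)
    signed = np.sign(offsets)[..., None] * ind
    return np.concatenate([ind, signed], axis=-1)


# -------------------------------------------------------------------------
# attention kernels

def _softmax_rows(logits: Tensor) -> Tensor:
    m = stop_gradient(logits.max(axis=-1, keepdims=True))
    e = (logits - m).exp()
    return e / e.sum(axis=-1, keepdims=True)


def dense_attention(q, k, v, rel_logits=None):
    """Reference softmax attention.  q (L, d_qk), k (S, d_qk), v (S, d_v);
    optional additive relative-position logits (L, S)."""
    t = any(isinstance(a, Tensor) for a in (q, k, v))
    q, k, v = ad.as_tensor(q), ad.as_tensor(k), ad.as_tensor(v)
    scale = 1.0 / np.sqrt(q.shape[-1])
    logits = (q @ k.transpose(1, 0)) * scale
    if rel_logits is not None:
        logits = logits + ad.as_tensor(rel_logits)
    out = _softmax_rows(logits) @ v
    return out if t else out.value


def chunked_attention(q, k, v, chunk_len: int, rel_logits=None):
    """Softmax attention computed over key chunks with running max and
    denominator accumulation (flash-style schedule).

    Numerically equal to :func:`dense_attention` for every chunk length;
    chunking changes the memory/compute schedule, never the values.
    """
    if chunk_len is None or chunk_len >= ad.as_tensor(k).shape[0]:
        return dense_attention(q, k, v, rel_logits)
    if chunk_len < 1:
        raise ValueError("chunk_len must be >= 1")
    t = any(isinstance(a, Tensor) for a in (q, k, v))
    q, k, v = ad.as_tensor(q), ad.as_tensor(k), ad.as_tensor(v)
    L = q.shape[0]
    S = k.shape[0]
    scale = 1.0 / np.sqrt(q.shape[-1])
    m_run = np.full((L, 1), -np.inf, dtype=q.value.dtype)
    num: Tensor | None = None     # running numerator (L, d_v)
    den: Tensor | None = None     # running denominator (L, 1)
    for lo in range(0, S, chunk_len):
        hi = min(lo + chunk_len, S)
        logits = (q @ k[lo:hi].transpose(1, 0)) * scale
        if rel_logits is not None:
            rl = ad.as_tensor(rel_logits)
            logits = logits + rl[:, lo:hi]
        m_new = np.maximum(m_run, logits.value.max(axis=-1, keepdims=True))
        e = (logits - Tensor(m_new)).exp()
        corr = Tensor(np.exp(m_run - m_new))   # rescale of previous chunks
        part_num = e @ v[lo:hi]
        part_den = e.sum(axis=-1, keepdims=True)
        if num is None:
            num, den = part_num, part_den
        else:
            num = num * corr + part_num
            den = den * corr + part_den
        m_run = m_new
    out = num / den
    return out if t else out.value


# -------------------------------------------------------------------------
# layers

class AttentionLayer(Module):
    """Pre-LayerNorm multi-head softmax attention + residual, followed by a
    pointwise feed-forward sublayer + residual."""

    def __init__(self, rng: np.random.Generator, cfg: AttentionConfig):
        d, H = cfg.d_model, cfg.heads
        self.cfg = cfg
        self.norm1 = LayerNorm(d)
        self.Wq = [Linear(rng, d, cfg.d_qk, bias=False) for _ in range(H)]
        self.Wk = [Linear(rng, d, cfg.d_qk, bias=False) for _ in range(H)]
        self.Wv = [Linear(rng, d, cfg.d_v, bias=False) for _ in range(H)]
        self.Wo = Linear(rng, d, d, bias=False)
        if cfg.pos_mode == "ENFORMER_REL":
            self.rel_w = [Param(lecun_normal(rng, (cfg.basis_size,),
                                             fan_in=cfg.basis_size))
                          for _ in range(H)]
        self.norm2 = LayerNorm(d)
        self.ff1 = Linear(rng, d, cfg.ff_expansion * d)
        self.ff2 = Linear(rng, cfg.ff_expansion * d, d)

    def _rel_logits(self, L: int, head: int) -> Tensor:
        offs = np.arange(L)[:, None] - np.arange(L)[None, :]
        basis = enformer_rel_basis(offs, self.cfg.basis_size)   # (L, L, F)
        F = basis.shape[-1]
        return (Tensor(basis.reshape(L * L, F)) @ self.rel_w[head]).reshape(L, L)

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        L = x.shape[0]
        z = self.norm1(x)
        heads = []
        for h in range(cfg.heads):
            q, k, v = self.Wq[h](z), self.Wk[h](z), self.Wv[h](z)
            if cfg.pos_mode == "ROPE":
                q = rope_encode(q, base=cfg.rope_base)
                k = rope_encode(k, base=cfg.rope_base)
            rel = None
            if cfg.pos_mode == "ENFORMER_REL":
                rel = self._rel_logits(L, h)
            heads.append(chunked_attention(q, k, v, cfg.chunk_len or L, rel))
        y = concat(heads, axis=1)
        x = x + self.Wo(y)
        return x + self.ff2(gelu(self.ff1(self.norm2(x))))


class UNetWrap(Module):
    """Pool → inner layers at coarse resolution → upsample with skips.

    Each round halves the length with max-pooling and saves a skip; after
    the inner stack, each round upsamples by nearest-neighbour repeat and
    combines additively with a pointwise linear of the skip.  Output
    length equals input length.
    """

    def __init__(self, rng: np.random.Generator, inner: list[Module],
                 d_model: int, pool_rounds: int = 1):
        self.inner = inner
        self.pool_rounds = pool_rounds
        self.up_proj = [Linear(rng, d_model, d_model) for _ in range(pool_rounds)]

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[0]
        if L % (2 ** self.pool_rounds) != 0:
            raise ValueError(f"length {L} not divisible by 2^{self.pool_rounds}")
        skips = []
        for _ in range(self.pool_rounds):
            skips.append(x)
            x = maxpool2(x)
        for layer in self.inner:
            x = layer(x)
        for proj in reversed(self.up_proj):
            skip = skips.pop()
            x = proj(x.repeat(2, axis=0)) + skip
        return x
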