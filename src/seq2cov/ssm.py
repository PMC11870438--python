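"""Selective state-space (Mamba-style) layers.

A selective SSM is a per-channel linear recurrence whose step size Δ_t,
input matrix B_t and readout C_t are projections of the current input —
content-dependent memory.  The diagonal continuous-time state matrix A is
discretised per step (Ā_t = exp(Δ_t A)); the recurrence

    h_t = Ā_t ⊙ h_{t-1} + B̄_t x_t,      y_t = ⟨C_t, h_t⟩

is evaluated either sequentially (the correctness oracle) or by an
associative parallel scan over the combine rule
(a₁,b₁)∘(a₂,b₂) = (a₁a₂, a₂b₁+b₂), identity (1, 0).

The bidirectional wrapper runs a second scan on the length-reversed
sequence with its own scan parameters but a *tied* input projection (the
forward and backward projections into the expanded internal space share
weights), optionally composed with a reverse-complement channel
permutation, and re-reverses the backward output before the shared output
projection.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, gelu, linear_scan, softplus
from .nn import Linear, Module, Param, RMSNorm, depthwise_conv1d, lecun_normal

__all__ = ["SSMConfig", "discretize", "ssm_scan_sequential",
           "ssm_scan_associative", "scan_combine", "SelectiveSSM",
           "MambaLayer"]


@dataclasses.dataclass
class SSMConfig:
    """Hyperparameters of one (bidirectional) Mamba layer.

    N is the state dimension, E the expansion factor of the projection
    from d_model into the layer's internal dimension D = E*d_model.
    """

    d_model: int
    N: int = 8
    E: int = 1
    conv_width: int = 4
    dt_rank: int | None = None       # low-rank Δ projection; default ceil(d/16)
    dt_min: float = 1e-3
    dt_max: float = 1e-1
    bidirectional: bool = True
    rc_perm: np.ndarray | None = None  # channel permutation for the backward branch
    zoh: bool = False                # full zero-order-hold for B̄ (else Euler)
    checkpoint_every: int | None = None

    @property
    def d_inner(self) -> int:
        return self.E * self.d_model

    @property
    def rank(self) -> int:
        return self.dt_rank if self.dt_rank is not None else -(-self.d_model // 16)


def scan_combine(e1: tuple[np.ndarray, np.ndarray],
                 e2: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """The associative combine: (a1,b1)∘(a2,b2) = (a1*a2, a2*b1 + b2)."""
    a1, b1 = e1
    a2, b2 = e2
    return a1 * a2, a2 * b1 + b2


def discretize(A, B_t, delta, zoh: bool = False):
    """Discretise the diagonal SSM: Ā = exp(Δ·A); B̄ by Euler (Δ·B) or
    zero-order hold ((Ā−1)/A · B).

    Shapes: A (D, N); B_t (L, N); delta (L, D).  Returns Ā, B̄ of shape
    (L, D, N).  Works on Tensors or ndarrays.
    """
    t = isinstance(A, Tensor) or isinstance(B_t, Tensor) or isinstance(delta, Tensor)
    A, B_t, delta = ad.as_tensor(A), ad.as_tensor(B_t), ad.as_tensor(delta)
    if np.any(delta.value <= 0):
        raise ValueError("step size Δ must be strictly positive")
    L, D = delta.shape
    dlt = delta.reshape(L, D, 1)
    dA = dlt * A.reshape(1, *A.shape)
    Abar = dA.exp()
    Bexp = B_t.reshape(L, 1, -1)
    if zoh:
        # (exp(ΔA) − 1)/A · B; A is strictly negative by construction so
        # the division is safe (Δ→0 limit recovers Δ·B)
        Bbar = (Abar - 1.0) / A.reshape(1, *A.shape) * Bexp
    else:
        Bbar = dlt * Bexp
    if not t:
        return Abar.value, Bbar.value
    return Abar, Bbar


def _readout(h, C_t):
    """y[t, d] = Σ_n h[t, d, n] C[t, n] for h (L, D, N), C (L, N)."""
    L, D, N = h.shape
    return (h * C_t.reshape(L, 1, N)).sum(axis=2)


def ssm_scan_sequential(x: np.ndarray, Abar: np.ndarray, Bbar: np.ndarray,
                        C_t: np.ndarray) -> np.ndarray:
    """Sequential oracle for the selective scan (numpy only, O(L·D·N)).

    x (L, D); Abar, Bbar (L, D, N); C_t (L, N) -> y (L, D).
    """
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite input to scan")
    L, D, N = Abar.shape
    y = np.empty((L, D))
    h = np.zeros((D, N))
    for t in range(L):
        h = Abar[t] * h + Bbar[t] * x[t, :, None]
        y[t] = h @ C_t[t]
    return y


def ssm_scan_associative(x, Abar, Bbar, C_t,
                         checkpoint_every: int | None = None):
    """Parallel-scan evaluation; same mapping as the sequential oracle.

    Accepts Tensors (differentiable; the scan's adjoint is a reverse-time
    scan) or ndarrays.  ``checkpoint_every`` sets the blocked-scan chunk
    size and never changes values.
    """
    t = isinstance(x, Tensor)
    x_, Ab, Bb, C_ = (ad.as_tensor(v) for v in (x, Abar, Bbar, C_t))
    if np.any(~np.isfinite(x_.value)):
        raise ValueError("non-finite input to scan")
    L, D, N = Ab.shape
    b = Bb * x_.reshape(L, D, 1)
    h = linear_scan(Ab, b, checkpoint_every=checkpoint_every)
    y = _readout(h, C_)
    return y if t else y.value


class SelectiveSSM(Module):
    """Input-dependent projections + diagonal SSM scan for one direction.

    A is parameterised as −exp(A_log) with A_log initialised to
    log(1..N) per channel; Δ positivity comes from a softplus whose bias
    is drawn so that initial Δ spans roughly [dt_min, dt_max].
    """

    def __init__(self, rng: np.random.Generator, cfg: SSMConfig):
        D, N, r = cfg.d_inner, cfg.N, cfg.rank
        self.cfg = cfg
        self.A_log = Param(np.tile(np.log(np.arange(1, N + 1.0)), (D, 1)))
        self.W_B = Param(lecun_normal(rng, (D, N)))
        self.W_C = Param(lecun_normal(rng, (D, N)))
        self.W_dt_down = Param(lecun_normal(rng, (D, r)))
        self.W_dt_up = Param(lecun_normal(rng, (r, D)))
        dt0 = np.exp(rng.uniform(np.log(cfg.dt_min), np.log(cfg.dt_max), D))
        self.b_dt = Param(np.log(np.expm1(dt0)))
        self.conv_w = Param(lecun_normal(rng, (cfg.conv_width, D), fan_in=cfg.conv_width))

    def __call__(self, u: Tensor) -> Tensor:
        cfg = self.cfg
        u = depthwise_conv1d(u, self.conv_w, causal=False)
        A = -(self.A_log.exp())
        delta = softplus(u @ self.W_dt_down @ self.W_dt_up + self.b_dt)
        B_t = u @ self.W_B
        C_t = u @ self.W_C
        Abar, Bbar = discretize(A, B_t, delta, zoh=cfg.zoh)
        return ssm_scan_associative(u, Abar, Bbar, C_t,
                                    checkpoint_every=cfg.checkpoint_every)


class MambaLayer(Module):
    """One residual (optionally bidirectional) selective-SSM block.

    RMSNorm → tied input projection (value + gate branches) → short
    depthwise conv + selective scan per direction → GeLU-gated merge →
    shared output projection → residual add.  Disabling
    ``cfg.bidirectional`` gives the causal layer used by generative
    models.
    """

    def __init__(self, rng: np.random.Generator, cfg: SSMConfig):
        d, D = cfg.d_model, cfg.d_inner
        self.cfg = cfg
        self.norm = RMSNorm(d)
        self.in_proj = Linear(rng, d, D, bias=False)    # tied across directions
        self.gate_proj = Linear(rng, d, D, bias=False)
        self.fwd = SelectiveSSM(rng, cfg)
        self.bwd = SelectiveSSM(rng, cfg) if cfg.bidirectional else None
        self.out_proj = Linear(rng, D, d, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        z = self.norm(x)
        u = z @ self.in_proj.W                # the tied projection
        y = self.fwd(u)
        if self.bwd is not None:
            ub = u
            if cfg.rc_perm is not None:
                ub = ub[:, np.asarray(cfg.rc_perm)]
            yb = self.bwd(ub.flip(0)).flip(0)
            if cfg.rc_perm is not None:
                inv = np.argsort(np.asarray(cfg.rc_perm))
                yb = yb[:, inv]
            y = y + yb
        y = y * gelu(self.gate_proj(z))
        return x + self.out_proj(y)
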