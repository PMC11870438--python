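"""Model assembly, loss algebra, equivariance diagnostics, schedule and
clipping contracts, and training-loop behaviour."""

import numpy as np
import pytest

from seq2cov import autodiff as ad
from seq2cov import seqdata as sd
from seq2cov import squash
from seq2cov.attention import UNetWrap
from seq2cov.model import (Adam, AttnSpec, MambaSpec, Model, ModelConfig,
                           TrainConfig, build_model, clip_gradients,
                           equivariance_gap, equivariance_penalty,
                           load_params, lr_schedule, poisson_multinomial_loss,
                           revcomp_tracks, train)
from seq2cov.seqdata import bin_coverage, revcomp_onehot
from seq2cov.ssm import MambaLayer

RNG = np.random.default_rng(23)


def _tiny_cfg(n_tracks=8, stack=None):
    return ModelConfig(n_tracks=n_tracks, d_model=16, window_len=2048,
                       stack=stack or [MambaSpec(N=4)])


# -- build ----------------------------------------------------------------

def test_build_deterministic():
    cfg = _tiny_cfg()
    a = build_model(cfg, seed=3).parameters()
    b = build_model(cfg, seed=3).parameters()
    assert a.keys() == b.keys()
    for k in a:
        assert np.array_equal(a[k].value, b[k].value)


def test_striped_config_layer_counts():
    cfg = _tiny_cfg(stack=[MambaSpec(), MambaSpec(), AttnSpec(d_qk=8)] * 2)
    m = build_model(cfg, seed=0)
    assert sum(isinstance(l, MambaLayer) for l in m.layers) == 4
    assert sum(isinstance(l, UNetWrap) for l in m.layers) == 2


def test_forward_shape_and_positive_rates():
    m = build_model(_tiny_cfg(), seed=1)
    oh = sd.one_hot_encode("".join(np.random.default_rng(0).choice(
        list("ACGT"), 2048)))
    pred = m.predict(oh)
    assert pred.shape == (64, 8)
    assert np.all(pred > 0)
    with pytest.raises(ValueError):
        m.predict(oh[:100])


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_tracks=2, window_len=1000, bin_width=32)


def test_model_config_from_yaml(tmp_path):
    p = tmp_path / "model.yaml"
    p.write_text(
        "n_tracks: 8\nd_model: 64\nwindow_len: 8192\n"
        "stack:\n"
        "  - {type: mamba, N: 8, E: 1, repeat: 2}\n"
        "  - {type: attn, pos_mode: ROPE, d_qk: 16}\n")
    cfg = ModelConfig.from_yaml(p)
    assert len(cfg.stack) == 3
    assert isinstance(cfg.stack[0], MambaSpec) and cfg.stack[0].N == 8
    assert isinstance(cfg.stack[2], AttnSpec) and cfg.stack[2].pos_mode == "ROPE"


def test_residual_zero_output_projection_layer_is_exact_noop():
    cfg = _tiny_cfg(stack=[MambaSpec(N=4), MambaSpec(N=4)])
    m = build_model(cfg, seed=2)
    oh = np.eye(4)[np.random.default_rng(1).integers(0, 4, 2048)].astype(float)
    base = m.predict(oh)
    m.layers[1].out_proj.W.value[:] = 0.0
    ablated = m.predict(oh)
    m2 = build_model(_tiny_cfg(stack=[MambaSpec(N=4)]), seed=2)
    # same trunk/first-layer params as the 2-layer build
    for k, p in m2.parameters().items():
        p.value[...] = m.parameters()[k].value
    assert np.array_equal(ablated, m2.predict(oh))
    assert not np.array_equal(base, ablated)


# -- loss ------------------------------------------------------------------

def test_loss_gradient_zero_at_data():
    counts = RNG.poisson(3.0, (20, 3)).astype(float) + 1.0
    for w in (1.0, 4.0):
        pred = ad.Tensor(counts.copy(), requires_grad=True)
        poisson_multinomial_loss(pred, counts, w=w).backward()
        assert np.abs(pred.grad).max() < 1e-6


def test_loss_w1_gradient_equals_per_bin_poisson():
    counts = RNG.poisson(2.0, (64, 3)).astype(float)
    rates = RNG.uniform(0.5, 5.0, (64, 3))
    p1 = ad.Tensor(rates.copy(), requires_grad=True)
    poisson_multinomial_loss(p1, counts, w=1.0).backward()
    p2 = ad.Tensor(rates.copy(), requires_grad=True)
    nll = (p2 - ad.Tensor(counts) * (p2 + 1e-9).log()).sum()
    nll.backward()
    rel = np.abs(p1.grad - p2.grad).max() / np.abs(p2.grad).max()
    assert rel < 1e-6


def test_loss_rejects_bad_inputs():
    with pytest.raises(ValueError):
        poisson_multinomial_loss(np.ones((4, 1)), -np.ones((4, 1)))
    with pytest.raises(ValueError):
        poisson_multinomial_loss(np.zeros((4, 1)), np.ones((4, 1)))


def test_loss_scalar_on_arrays():
    val = poisson_multinomial_loss(np.ones((8, 2)), np.ones((8, 2)), w=4.0)
    assert isinstance(val, float)


# -- equivariance ----------------------------------------------------------

def _toy_equivariant(meta):
    """A strictly revcomp-equivariant toy predictor built from an arbitrary
    strand-specific feature φ: fwd = φ(x), rev = reverse(φ(revcomp x)),
    unstranded = their sum."""

    def phi(oh):
        sig = oh[:, 0] * 1.0 + oh[:, 2] * 0.5 + 0.1      # asymmetric in bases
        b = bin_coverage(sig, 32)
        return np.convolve(b, [0.25, 0.5, 0.25], mode="same")

    def model(oh):
        f = phi(oh)
        r = phi(revcomp_onehot(oh))[::-1]
        return np.stack([f, r, f + r], axis=1)

    return model


def test_toy_equivariant_model_has_zero_gap():
    meta = [sd.TrackMeta("f", sd.Assay.CAGE, sd.Strand.FWD, "p"),
            sd.TrackMeta("r", sd.Assay.CAGE, sd.Strand.REV, "p"),
            sd.TrackMeta("u", sd.Assay.DNASE, sd.Strand.UNSTRANDED)]
    oh = sd.one_hot_encode("".join(np.random.default_rng(3).choice(
        list("ACGT"), 1024)))
    gap = equivariance_gap(_toy_equivariant(meta), oh, meta)
    assert gap < 1e-5


def test_random_model_has_positive_gap_and_strand_symmetry(tiny_corpus):
    m = build_model(_tiny_cfg(), seed=7)
    meta = tiny_corpus.counts[0].meta
    oh = tiny_corpus.windows[0].onehot
    gap = equivariance_gap(m.predict, oh, meta)
    assert gap > 1e-3
    gap_rc = equivariance_gap(m.predict, revcomp_onehot(oh), meta)
    assert np.isclose(gap, gap_rc, rtol=1e-10)


def test_equivariance_penalty_matches_gap_and_is_differentiable(tiny_corpus):
    m = build_model(_tiny_cfg(), seed=9)
    meta = tiny_corpus.counts[0].meta
    oh = tiny_corpus.windows[0].onehot
    coeff = 1e-2
    pen = equivariance_penalty(m, oh, meta, coeff=coeff)
    gap = equivariance_gap(m.predict, oh, meta)
    assert np.isclose(pen.value, coeff * gap ** 2, rtol=1e-6)
    m.zero_grad()
    pen.backward()
    grads = [p.grad for p in m.parameters().values() if p.grad is not None]
    assert grads and any(np.abs(g).max() > 0 for g in grads)


def test_revcomp_tracks_is_involution(tiny_corpus):
    meta = tiny_corpus.counts[0].meta
    pred = RNG.uniform(0, 2, (16, len(meta)))
    assert np.array_equal(revcomp_tracks(revcomp_tracks(pred, meta), meta), pred)


# -- schedule and clipping -------------------------------------------------

def test_lr_schedule_linear_warmup():
    cfg = TrainConfig()
    assert lr_schedule(0, cfg) == 0.0
    assert lr_schedule(5000, cfg) == pytest.approx(5e-5)
    assert lr_schedule(10_000, cfg) == pytest.approx(1e-4)
    assert lr_schedule(1_000_000, cfg) == pytest.approx(1e-4)
    with pytest.raises(ValueError):
        lr_schedule(-1, cfg)


def test_clip_single_block_rescaled():
    cfg = TrainConfig()
    g = {"head.W": np.full(16, 5.0)}        # norm 20
    out = clip_gradients(g, cfg)
    assert np.isclose(np.linalg.norm(out["head.W"]), 5.0)


def test_clip_idempotent_on_compliant():
    cfg = TrainConfig()
    g = {"head.W": np.full(4, 0.1), "trunk.blocks.0.W": np.full(4, 0.2)}
    out = clip_gradients(g, cfg)
    for k in g:
        assert np.array_equal(out[k], g[k])


def test_clip_two_stage_global():
    cfg = TrainConfig()
    # 8 blocks each exactly at block norm 5 -> global norm sqrt(200) ≈ 14.1
    g = {f"layers.{i}.W": np.full(25, 1.0) for i in range(8)}
    out = clip_gradients(g, cfg)
    block_norms = [np.linalg.norm(v) for v in out.values()]
    assert np.allclose(block_norms, 5.0 * 10.0 / np.sqrt(200.0))
    total = np.sqrt(sum(np.sum(v ** 2) for v in out.values()))
    assert np.isclose(total, 10.0)


def test_clip_groups_parameters_within_a_block():
    cfg = TrainConfig()
    g = {"layers.0.a": np.full(8, 2.0), "layers.0.b": np.full(8, 2.0),
         "layers.1.a": np.zeros(4)}
    out = clip_gradients(g, cfg)
    joint = np.sqrt(np.sum(out["layers.0.a"] ** 2) + np.sum(out["layers.0.b"] ** 2))
    assert np.isclose(joint, 5.0)
    assert np.array_equal(out["layers.1.a"], g["layers.1.a"])


def test_clip_rejects_nan():
    with pytest.raises(FloatingPointError):
        clip_gradients({"w": np.array([np.nan])}, TrainConfig())


# -- training loop ---------------------------------------------------------

def _train_setup(tiny_corpus):
    targets = [squash(ts.values) for ts in tiny_corpus.counts]
    meta = tiny_corpus.counts[0].meta
    return tiny_corpus.windows, targets, meta


def test_epoch_performs_ceil_n_over_2_steps(tiny_corpus):
    windows, targets, meta = _train_setup(tiny_corpus)
    m = build_model(_tiny_cfg(), seed=1).astype(np.float32)
    cfg = TrainConfig(crop_bins=8, max_epochs=1, warmup_steps=10, lr=1e-3,
                      patience=99)
    res = train(m, windows, targets, meta, [0, 1, 2, 3, 4], [5], cfg, seed=0)
    assert res.steps == int(np.ceil(5 / 2))


def test_training_is_deterministic(tiny_corpus):
    windows, targets, meta = _train_setup(tiny_corpus)
    losses = []
    for rep in range(2):
        m = build_model(_tiny_cfg(), seed=1).astype(np.float32)
        cfg = TrainConfig(crop_bins=8, max_steps=5, warmup_steps=10, lr=1e-3,
                          patience=99, max_epochs=99)
        res = train(m, windows, targets, meta, [0, 1, 2, 3], [4], cfg, seed=0,
                    log_every=1)
        losses.append([h["loss"] for h in res.history if "loss" in h])
    assert losses[0] == losses[1]


def test_loss_decreases_on_fixed_batch(tiny_corpus):
    windows, targets, meta = _train_setup(tiny_corpus)
    m = build_model(_tiny_cfg(), seed=2).astype(np.float32)
    cfg = TrainConfig(crop_bins=8, max_steps=50, warmup_steps=10, lr=2e-3,
                      patience=99, max_epochs=999, augment=False)
    res = train(m, windows, targets, meta, [0, 1], [2], cfg, seed=0, log_every=1)
    first = np.mean([h["loss"] for h in res.history[:5]])
    last = np.mean([h["loss"] for h in res.history[-5:]])
    assert last < first


def test_train_rejects_bad_sets(tiny_corpus):
    windows, targets, meta = _train_setup(tiny_corpus)
    m = build_model(_tiny_cfg(), seed=1)
    cfg = TrainConfig(crop_bins=8)
    with pytest.raises(ValueError):
        train(m, windows, targets, meta, [], [0], cfg, seed=0)
    with pytest.raises(ValueError):
        train(m, windows, targets, meta, [0, 1], [1], cfg, seed=0)


def test_load_params_roundtrip():
    m = build_model(_tiny_cfg(), seed=5)
    snap = {k: p.value.copy() for k, p in m.parameters().items()}
    for p in m.parameters().values():
        p.value += 1.0
    load_params(m, snap)
    for k, p in m.parameters().items():
        assert np.array_equal(p.value, snap[k])


def test_adam_moves_toward_minimum():
    cfg = TrainConfig(lr=0.1)
    p = ad.Tensor(np.array([5.0]), requires_grad=True)
    opt = Adam({"p": p}, cfg)
    for _ in range(200):
        opt.step({"p": p}, {"p": 2 * p.value}, lr=0.1)   # d/dp p^2
    assert abs(p.value[0]) < 0.1
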