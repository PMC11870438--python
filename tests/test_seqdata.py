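"""Data-module contracts: encoding, squash, binning, cropping,
augmentation, splits, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seq2cov import seqdata as sd
from seq2cov.seqdata import (Assay, DataConfig, Role, SequenceWindow, Strand,
                             TrackMeta, TrackSet)


# -- one-hot encoding ------------------------------------------------------

def test_one_hot_basics():
    assert np.array_equal(sd.one_hot_encode("ACGT"), np.eye(4))
    assert np.array_equal(sd.one_hot_encode("N"), np.zeros((1, 4)))
    assert np.array_equal(sd.one_hot_encode("acgt"), sd.one_hot_encode("ACGT"))


def test_one_hot_rejects_with_position():
    with pytest.raises(ValueError, match="position 2"):
        sd.one_hot_encode("ACXT")


def test_one_hot_roundtrip():
    seq = "ACGTNNACGT"
    assert sd.one_hot_decode(sd.one_hot_encode(seq)) == seq


def test_revcomp_onehot_matches_string_revcomp():
    seq = "AACGTNGT"
    assert sd.one_hot_decode(sd.revcomp_onehot(sd.one_hot_encode(seq))) == \
        sd.reverse_complement(seq)


# -- squash ----------------------------------------------------------------

def test_squash_examples():
    assert sd.squash(0.0) == 0.0
    assert sd.squash(16.0) == 8.0          # 16^(3/4), below-threshold branch
    # above threshold: evaluate both branch terms independently and sum
    x = 1e6
    p = x ** 0.75
    expected = min(p, 384.0) + max(0.0, p - 384.0)
    assert np.isclose(sd.squash(x), expected, rtol=1e-12)
    assert np.isclose(expected, p)          # the printed form reduces to x^(3/4)


def test_squash_rejects_negative():
    with pytest.raises(ValueError):
        sd.squash(-1.0)
    with pytest.raises(ValueError):
        sd.unsquash(-0.5)


def test_squash_monotone_and_invertible_on_log_grid():
    x = np.concatenate([[0.0], np.logspace(-6, 7, 200)])
    y = sd.squash(x)
    assert np.all(np.diff(y) > 0)
    back = sd.unsquash(y)
    assert np.allclose(back, x, rtol=1e-6, atol=1e-12)


def test_squash_soft_clip_variant_roundtrip():
    x = np.logspace(0, 7, 50)
    y = sd.squash(x, clip_exponent=0.5)
    assert np.all(np.diff(y) > 0)
    # above threshold the soft-clip grows slower than the printed form
    assert y[-1] < sd.squash(x[-1])
    assert np.allclose(sd.unsquash(y, clip_exponent=0.5), x, rtol=1e-9)


# -- binning / cropping ----------------------------------------------------

def test_bin_coverage_examples():
    assert np.array_equal(sd.bin_coverage(np.ones(64), 32), [32.0, 32.0])
    assert np.array_equal(sd.bin_coverage(np.zeros(96), 32), np.zeros(3))
    imp = np.zeros(96)
    imp[33] = 5.0
    assert np.array_equal(sd.bin_coverage(imp, 32), [0.0, 5.0, 0.0])
    with pytest.raises(ValueError):
        sd.bin_coverage(np.ones(65), 32)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(1, 8), st.integers(1, 6), st.integers(0, 10_000))
def test_bin_coverage_conserves_total(nbins, width, seed):
    r = np.random.default_rng(seed)
    per_base = r.poisson(2.0, nbins * width).astype(float)
    assert sd.bin_coverage(per_base, width).sum() == per_base.sum()


def _tracks(values, bin_width=32):
    meta = [TrackMeta("fwd", Assay.CAGE, Strand.FWD, "p"),
            TrackMeta("rev", Assay.CAGE, Strand.REV, "p")]
    return TrackSet(np.asarray(values, float), bin_width, meta)


def test_crop_bins():
    ts = _tracks(np.arange(24).reshape(12, 2))
    out = sd.crop_bins(ts, 2)
    assert out.n_bins == 8
    assert np.array_equal(out.values, ts.values[2:10])
    assert sd.crop_bins(ts, 0) is ts
    with pytest.raises(ValueError):
        sd.crop_bins(_tracks(np.zeros((10, 2))), 5)


def test_crop_matches_reference_geometry():
    ts = _tracks(np.zeros((12288, 2)))
    assert sd.crop_bins(ts, 2048).n_bins == 8192


# -- augmentation ----------------------------------------------------------

def test_revcomp_augment_exchanges_pairs():
    win = SequenceWindow("w", 0, sd.one_hot_encode("AAAC"))
    ts = TrackSet(np.array([[1.0, 3.0], [2.0, 4.0]]), 2, _tracks(np.zeros((1, 2)), 2).meta)
    w2, t2 = sd.revcomp_augment(win, ts)
    assert w2.sequence() == "GTTT"
    assert np.array_equal(t2.values, [[4.0, 2.0], [3.0, 1.0]])


def test_revcomp_augment_is_involution(tiny_corpus):
    win = tiny_corpus.windows[0]
    ts = tiny_corpus.counts[0]
    w2, t2 = sd.revcomp_augment(*sd.revcomp_augment(win, ts))
    assert np.array_equal(w2.onehot, win.onehot)
    assert np.array_equal(t2.values, ts.values)


def test_revcomp_augment_unstranded_reversed_only():
    meta = [TrackMeta("u", Assay.DNASE, Strand.UNSTRANDED)]
    ts = TrackSet(np.array([[1.0], [2.0], [3.0]]), 2,  meta)
    win = SequenceWindow("w", 0, sd.one_hot_encode("ACGTAA"))
    _, t2 = sd.revcomp_augment(win, ts)
    assert np.array_equal(t2.values, [[3.0], [2.0], [1.0]])


def test_revcomp_augment_rejects_broken_pairing():
    meta = [TrackMeta("a", Assay.CAGE, Strand.FWD, "p"),
            TrackMeta("b", Assay.CAGE, Strand.FWD, "q")]
    ts = TrackSet(np.zeros((2, 2)), 2, meta)
    win = SequenceWindow("w", 0, sd.one_hot_encode("ACGT"))
    with pytest.raises(ValueError):
        sd.revcomp_augment(win, ts)


def test_shift_augment():
    win = SequenceWindow("w", 0, sd.one_hot_encode("ACGTACGT"))
    assert sd.shift_augment(win, 0) is win
    s3 = sd.shift_augment(win, 3)
    assert np.array_equal(s3.onehot[:3], np.zeros((3, 4)))
    assert np.array_equal(s3.onehot[3:], win.onehot[:-3])
    # vacated rows reduce the total by exactly |shift|
    assert s3.onehot.sum() == win.onehot.sum() - 3
    sm = sd.shift_augment(win, -2)
    assert np.array_equal(sm.onehot[-2:], np.zeros((2, 4)))
    with pytest.raises(ValueError):
        sd.shift_augment(win, 4)


# -- splits ----------------------------------------------------------------

def test_make_splits_partition_properties():
    cfg = DataConfig(window_len=2048, bin_width=32, crop_bins=4)
    splits = sd.make_splits(40, cfg, seed=3)
    assert len(splits) == 4
    test_folds = set()
    val_folds = set()
    for sa in splits:
        tr = set(sa.windows_with_role(Role.TRAIN))
        va = set(sa.windows_with_role(Role.VAL))
        te = set(sa.windows_with_role(Role.TEST))
        assert tr | va | te == set(range(40))
        assert not (tr & va or tr & te or va & te)
        test_folds.add(frozenset(te))
        val_folds.add(frozenset(va))
        roles = list(sa.role_of_fold.values())
        assert roles.count(Role.VAL) == 1 and roles.count(Role.TEST) == 1
    assert len(test_folds) == 4 and len(val_folds) == 4


def test_make_splits_fold_sizes_and_determinism():
    cfg = DataConfig(window_len=2048, bin_width=32, crop_bins=4)
    a = sd.make_splits(12, cfg, seed=9)
    counts = np.bincount(a[0].fold_of_window)
    assert np.array_equal(counts, [2] * 6)
    b = sd.make_splits(12, cfg, seed=9)
    assert np.array_equal(a[0].fold_of_window, b[0].fold_of_window)
    sizes = np.bincount(sd.make_splits(40, cfg, seed=1)[0].fold_of_window)
    assert sizes.max() - sizes.min() <= 1
    with pytest.raises(ValueError):
        sd.make_splits(5, cfg, seed=0)


def test_data_config_from_yaml(tmp_path):
    p = tmp_path / "data.yaml"
    p.write_text("window_len: 4096\nbin_width: 32\ncrop_bins: 8\n"
                 "split_ratio: [4, 1, 1]\n")
    cfg = DataConfig.from_yaml(p)
    assert cfg.window_len == 4096 and cfg.crop_bins == 8
    assert cfg.split_ratio == (4, 1, 1)
    assert cfg.squash_threshold == 384.0        # defaults preserved


def test_data_config_invariants():
    with pytest.raises(ValueError):
        DataConfig(window_len=100, bin_width=32)
    with pytest.raises(ValueError):
        DataConfig(split_ratio=(3, 1, 1))


# -- file I/O --------------------------------------------------------------

def test_fasta_roundtrip(tmp_path):
    recs = {"w0": "ACGTN" * 40, "w1": "TTTTACGT"}
    p = tmp_path / "x.fa"
    sd.write_fasta(p, recs)
    assert sd.read_fasta(p) == recs


def test_bedgraph_roundtrip_consistent_with_binning(tmp_path):
    p = tmp_path / "t.bedgraph"
    binned = np.array([3.0, 0.0, 7.5])
    sd.write_bedgraph(p, "w0", 0, binned, 32)
    per_base = sd.read_bedgraph(p, "w0", 0, 96)
    # interval values are per-bp, so re-binning scales by the bin width
    assert np.allclose(sd.bin_coverage(per_base, 32), binned * 32)


def test_bedgraph_interval_to_bins():
    import io
    # interval [0, 64) at value 1 -> per-base ones -> bins of 32
    per_base = np.zeros(96)
    per_base[:64] = 1.0
    assert np.array_equal(sd.bin_coverage(per_base, 32), [32.0, 32.0, 0.0])


def test_bedgraph_rejects_malformed_with_line_number(tmp_path):
    p = tmp_path / "bad.bedgraph"
    p.write_text("w0\t0\t32\t1.0\nw0\tnot_an_int\t64\t2.0\n")
    with pytest.raises(ValueError, match=":2"):
        sd.read_bedgraph(p, "w0", 0, 96)


def test_track_meta_and_matrix_roundtrip(tmp_path, tiny_corpus):
    meta = tiny_corpus.counts[0].meta
    mp = tmp_path / "meta.tsv"
    sd.write_track_meta(mp, meta)
    back = sd.read_track_meta(mp)
    assert [(m.track_id, m.assay, m.strand, m.pair_id) for m in back] == \
        [(m.track_id, m.assay, m.strand, m.pair_id) for m in meta]
    xp = tmp_path / "mat.tsv"
    sd.write_track_matrix(xp, tiny_corpus.counts[0], "w0")
    got = sd.read_track_matrix(xp, meta, 32)["w0"]
    assert np.allclose(got.values, tiny_corpus.counts[0].values)


def test_vcf_roundtrip_and_symbolic_rejection(tmp_path):
    p = tmp_path / "v.vcf"
    recs = [("w0", 100, "v1", "A", "G"), ("w1", 5, "v2", "C", "T")]
    sd.write_vcf(p, recs)
    assert sd.read_vcf(p) == recs
    bad = tmp_path / "bad.vcf"
    bad.write_text("##fileformat=VCFv4.2\n"
                   "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                   "w0\t10\tsv1\tA\t<DEL>\t.\tPASS\t.\n")
    with pytest.raises(ValueError, match="record 1"):
        sd.read_vcf(bad)


def test_track_meta_validation():
    with pytest.raises(ValueError):
        TrackMeta("x", Assay.CAGE, Strand.FWD)          # stranded needs pair
    with pytest.raises(ValueError):
        TrackMeta("x", Assay.DNASE, Strand.UNSTRANDED, "p")
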