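"""Seeded synthetic regulatory genomes with known causal structure.

Every other module is testable against this generator without downloads.
A corpus consists of random DNA windows in which occurrences of a small
set of consensus motifs (on either strand) deterministically shape
per-assay Poisson rate fields:

* CAGE-like tracks get a point source at the motif (a TSS proxy), on the
  strand of the match;
* RNA-like tracks get a constant block extending downstream of the motif;
* 3' RNA-like tracks get a point source at the downstream end of that
  block;
* DNase-like tracks get a smooth symmetric peak (unstranded);
* an OTHER track carries background only (a null track).

The rate field is a pure function of the sequence: matches are re-scanned
rather than remembered, so variant effects computed as rate(alt) −
rate(ref) are exactly consistent with the generative model, and
reverse-complementing the sequence while exchanging forward/reverse track
pairs reproduces the rates exactly (strand-exchange symmetry).  Observed
coverage is Poisson-sampled from the rates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqdata import (
    Assay,
    SequenceWindow,
    Strand,
    TrackMeta,
    TrackSet,
    one_hot_encode,
    reverse_complement,
    write_bedgraph,
    write_fasta,
    write_track_meta,
    write_vcf,
)

__all__ = ["MotifEffect", "SyntheticSpec", "Corpus", "rate_field",
           "generate_corpus", "generate_variants", "write_corpus",
           "default_track_meta"]


@dataclasses.dataclass
class MotifEffect:
    """A consensus motif and the per-assay kernels its matches induce.

    Each kernel maps a bin offset (relative to the motif's bin, oriented
    downstream for the match strand) to an added Poisson rate.
    """

    consensus: str
    # {assay: (offsets ndarray[int], amplitudes ndarray[float])}
    kernels: dict[Assay, tuple[np.ndarray, np.ndarray]]


def _default_motifs() -> list[MotifEffect]:
    off = np.arange
    rna_span = off(1, 25)
    dnase_off = off(-8, 9)
    # amplitudes quantized to multiples of 1/64 so that overlapping-kernel
    # sums are exact in float64 regardless of summation order; this keeps
    # the strand-exchange symmetry of the rates bit-exact
    dnase_amp = np.round(64 * 6.0 * np.exp(-0.5 * (dnase_off / 3.0) ** 2)) / 64
    return [
        MotifEffect(
            consensus="TATAAGCG",
            kernels={
                Assay.CAGE: (np.array([0, 1]), np.array([12.0, 4.0])),
                Assay.RNA: (rna_span, np.full(rna_span.size, 3.0)),
                Assay.RNA3P: (np.array([24]), np.array([8.0])),
                Assay.DNASE: (dnase_off, dnase_amp),
            },
        )
    ]


def default_track_meta() -> list[TrackMeta]:
    """The eight-track desk-scale panel: three strand-oriented pairs plus
    two unstranded tracks."""
    return [
        TrackMeta("cage_fwd", Assay.CAGE, Strand.FWD, "cage"),
        TrackMeta("cage_rev", Assay.CAGE, Strand.REV, "cage"),
        TrackMeta("rna_fwd", Assay.RNA, Strand.FWD, "rna"),
        TrackMeta("rna_rev", Assay.RNA, Strand.REV, "rna"),
        TrackMeta("rna3p_fwd", Assay.RNA3P, Strand.FWD, "rna3p"),
        TrackMeta("rna3p_rev", Assay.RNA3P, Strand.REV, "rna3p"),
        TrackMeta("dnase", Assay.DNASE, Strand.UNSTRANDED),
        TrackMeta("other", Assay.OTHER, Strand.UNSTRANDED),
    ]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the synthetic corpus.

    Defaults are the desk-scale study conditions: 8,192-bp windows at
    32-bp bins with eight tracks, background 0.5 counts/bin, about three
    planted motif instances per window.
    """

    n_windows: int = 64
    window_len: int = 8_192
    bin_width: int = 32
    background_rate: float = 0.5
    motifs: list[MotifEffect] = dataclasses.field(default_factory=_default_motifs)
    tracks: list[TrackMeta] = dataclasses.field(default_factory=default_track_meta)
    mean_instances: float = 3.0
    edge_margin_bins: int = 32  # keep planted motifs out of the cropped edges
    n_effect_variants: int = 24
    n_null_variants: int = 24
    seed: int = 0

    @property
    def n_bins(self) -> int:
        return self.window_len // self.bin_width

    def __post_init__(self):
        if self.window_len % self.bin_width != 0:
            raise ValueError("window_len must be divisible by bin_width")
        for m in self.motifs:
            if len(m.consensus) > self.window_len:
                raise ValueError(f"motif {m.consensus} longer than window")


@dataclasses.dataclass
class Corpus:
    spec: SyntheticSpec
    windows: list[SequenceWindow]
    counts: list[TrackSet]       # Poisson-sampled observed coverage
    rates: list[np.ndarray]      # (B, T) ground-truth rate fields


def _find_matches(seq: str, consensus: str) -> list[tuple[int, int]]:
    """All exact matches of ``consensus`` on both strands of ``seq``.

    Returns (start, strand) with strand +1/-1; for a minus-strand match,
    ``start`` is the leftmost base of the match on the given sequence.
    """
    hits = []
    rc = reverse_complement(consensus)
    k = len(consensus)
    for i in range(len(seq) - k + 1):
        sub = seq[i:i + k]
        if sub == consensus:
            hits.append((i, +1))
        if sub == rc:
            hits.append((i, -1))
    return hits


def rate_field(seq: str, spec: SyntheticSpec) -> np.ndarray:
    """Deterministic (B, T) ground-truth rate field for a window sequence.

    A plus-strand match at base p anchors its kernels at bin p//bin_width
    with downstream = increasing bins, contributing to FWD tracks of each
    stranded assay; a minus-strand match anchors at the bin of its
    rightmost base with downstream = decreasing bins, contributing to REV
    tracks.  Unstranded assays receive both orientations.  This
    construction makes revcomp + pair-exchange an exact symmetry of the
    rates.
    """
    B, T = spec.n_bins, len(spec.tracks)
    rates = np.full((B, T), spec.background_rate, dtype=np.float64)
    cols: dict[tuple[Assay, Strand], list[int]] = {}
    for j, m in enumerate(spec.tracks):
        cols.setdefault((m.assay, m.strand), []).append(j)
    for motif in spec.motifs:
        k = len(motif.consensus)
        for seq_start, strand in _find_matches(seq, motif.consensus):
            if strand > 0:
                anchor = seq_start // spec.bin_width
            else:
                anchor = (seq_start + k - 1) // spec.bin_width
            for assay, (offsets, amps) in motif.kernels.items():
                bins = anchor + strand * offsets
                ok = (bins >= 0) & (bins < B)
                want = Strand.FWD if strand > 0 else Strand.REV
                targets = cols.get((assay, want), []) + cols.get((assay, Strand.UNSTRANDED), [])
                for j in targets:
                    np.add.at(rates[:, j], bins[ok], amps[ok])
    return rates


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _plant(seq: list[str], motif: str, pos: int, strand: int) -> None:
    ins = motif if strand > 0 else reverse_complement(motif)
    seq[pos:pos + len(ins)] = list(ins)


def generate_corpus(spec: SyntheticSpec) -> Corpus:
    """Generate windows, ground-truth rates, and Poisson-sampled coverage."""
    rng = np.random.default_rng(spec.seed)
    windows, counts, rates = [], [], []
    margin = spec.edge_margin_bins * spec.bin_width
    for w in range(spec.n_windows):
        seq = list(_random_sequence(rng, spec.window_len))
        n_inst = (1 + rng.poisson(max(spec.mean_instances - 1, 0.0))
                  if spec.motifs else 0)
        for _ in range(n_inst):
            motif = spec.motifs[rng.integers(len(spec.motifs))]
            k = len(motif.consensus)
            lo, hi = margin, spec.window_len - margin - k
            pos = int(rng.integers(lo, hi))
            _plant(seq, motif.consensus, pos, 1 if rng.random() < 0.5 else -1)
        seq = "".join(seq)
        r = rate_field(seq, spec)
        c = rng.poisson(r).astype(np.float64)
        windows.append(SequenceWindow(f"synth{w}", 0, one_hot_encode(seq)))
        counts.append(TrackSet(c, spec.bin_width, list(spec.tracks)))
        rates.append(r)
    return Corpus(spec, windows, counts, rates)


def generate_variants(spec: SyntheticSpec, corpus: Corpus
                      ) -> list[dict]:
    """Plant effect and null variants with exact ground-truth rate deltas.

    Effect variants substitute a base inside a motif match (destroying it);
    null variants substitute a background base at least one motif-length
    away from any match.  The truth effect is the total rate change over
    the window, recomputed from the rate field, so negatives are exactly
    zero-effect by verification rather than by assumption.
    """
    rng = np.random.default_rng(spec.seed + 101)
    margin = spec.edge_margin_bins * spec.bin_width
    variants: list[dict] = []
    order = rng.permutation(spec.n_windows)
    widx = 0

    def next_window():
        nonlocal widx
        w = int(order[widx % spec.n_windows])
        widx += 1
        return w

    def true_delta(seq_ref: str, pos: int, alt: str) -> np.ndarray:
        seq_alt = seq_ref[:pos] + alt + seq_ref[pos + 1:]
        return rate_field(seq_alt, spec) - rate_field(seq_ref, spec)

    n_made = 0
    guard = 0
    while n_made < spec.n_effect_variants and guard < 50 * spec.n_effect_variants:
        guard += 1
        w = next_window()
        seq = corpus.windows[w].sequence()
        hits = [h for m in spec.motifs for h in _find_matches(seq, m.consensus)
                if margin <= h[0] < spec.window_len - margin]
        if not hits:
            continue
        start, strand = hits[rng.integers(len(hits))]
        klen = len(spec.motifs[0].consensus)
        pos = start + int(rng.integers(klen))
        ref = seq[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        if alt == ref:
            raise ValueError("effect variant with alt == ref")
        delta = true_delta(seq, pos, alt)
        variants.append({
            "id": f"eff{n_made}", "window": w, "pos": pos, "ref": ref, "alt": str(alt),
            "effect": float(delta.sum()), "label": 1,
        })
        n_made += 1

    n_made = 0
    guard = 0
    while n_made < spec.n_null_variants and guard < 200 * spec.n_null_variants:
        guard += 1
        w = next_window()
        seq = corpus.windows[w].sequence()
        pos = int(rng.integers(margin, spec.window_len - margin))
        ref = seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        delta = true_delta(seq, pos, alt)
        if np.any(delta != 0.0):
            continue  # touched or created a motif; not a null
        variants.append({
            "id": f"null{n_made}", "window": w, "pos": pos, "ref": ref, "alt": alt,
            "effect": 0.0, "label": 0,
        })
        n_made += 1
    return variants


def write_corpus(corpus: Corpus, out_dir: str | Path,
                 variants: Sequence[dict] | None = None) -> None:
    """Write the corpus in the standard formats read by the data module:
    FASTA sequences, per-track BedGraph coverage, TSV metadata and
    ground-truth rates, and (optionally) a VCF plus truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = corpus.spec
    write_fasta(out / "windows.fa",
                {w.chrom: w.sequence() for w in corpus.windows})
    write_track_meta(out / "tracks.tsv", spec.tracks)
    (out / "coverage").mkdir(exist_ok=True)
    for w, ts in zip(corpus.windows, corpus.counts):
        for j, m in enumerate(ts.meta):
            write_bedgraph(out / "coverage" / f"{w.chrom}.{m.track_id}.bedgraph",
                           w.chrom, w.start, ts.values[:, j], ts.bin_width)
    np.savetxt(out / "true_rates.tsv",
               np.concatenate([r for r in corpus.rates], axis=0),
               delimiter="\t", fmt="%.6g",
               header="\t".join(m.track_id for m in spec.tracks))
    if variants is not None:
        write_vcf(out / "variants.vcf",
                  [(corpus.windows[v["window"]].chrom, v["pos"], v["id"],
                    v["ref"], v["alt"]) for v in variants],
                  contigs={w.chrom: w.length for w in corpus.windows})
        import pandas as pd

        pd.DataFrame(variants).to_csv(out / "variants_truth.tsv", sep="\t", index=False)
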