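"""Sequence windows, coverage tracks, transforms, augmentation, and file I/O.

This module owns everything between files on disk and the tensors the
models consume: one-hot encoding of fixed-length DNA windows, the squash
transform applied to coverage before modelling, 32-bp binning and edge
cropping, reverse-complement and small-shift training augmentations, and
the fold/split bookkeeping used for cross-validated training.

Coordinates are 0-based half-open throughout (BedGraph native convention).
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Assay",
    "Strand",
    "SequenceWindow",
    "TrackMeta",
    "TrackSet",
    "DataConfig",
    "SplitAssignment",
    "Role",
    "one_hot_encode",
    "one_hot_decode",
    "reverse_complement",
    "squash",
    "unsquash",
    "bin_coverage",
    "crop_bins",
    "revcomp_augment",
    "shift_augment",
    "make_splits",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_track_meta",
    "write_track_meta",
    "read_track_matrix",
    "write_track_matrix",
    "read_vcf",
    "write_vcf",
]

# canonical column order of the one-hot encoding
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class Assay(str, enum.Enum):
    RNA = "RNA"
    CAGE = "CAGE"
    DNASE = "DNASE"
    RNA3P = "RNA3P"
    OTHER = "OTHER"


class Strand(str, enum.Enum):
    FWD = "FWD"
    REV = "REV"
    UNSTRANDED = "UNSTRANDED"


class Role(str, enum.Enum):
    TRAIN = "TRAIN"
    VAL = "VAL"
    TEST = "TEST"


@dataclasses.dataclass
class SequenceWindow:
    """A fixed-length genomic window with its one-hot encoding.

    ``onehot`` has shape (L, 4) with columns A,C,G,T; rows are one-hot for
    determined bases and all-zero for ambiguous (N) or shift-vacated
    positions.
    """

    chrom: str
    start: int
    onehot: np.ndarray

    def __post_init__(self):
        self.onehot = np.asarray(self.onehot, dtype=np.float64)
        if self.onehot.ndim != 2 or self.onehot.shape[1] != 4:
            raise ValueError(f"onehot must be (L, 4), got {self.onehot.shape}")
        rowsum = self.onehot.sum(axis=1)
        if not np.all((rowsum == 0) | (rowsum == 1)):
            raise ValueError("one-hot rows must sum to 0 or 1")

    @property
    def length(self) -> int:
        return self.onehot.shape[0]

    @property
    def end(self) -> int:
        return self.start + self.length

    def sequence(self) -> str:
        return one_hot_decode(self.onehot)


@dataclasses.dataclass
class TrackMeta:
    """Per-track metadata: assay class, strand orientation, pairing.

    ``pair_id`` links a FWD track to its REV partner; it is present exactly
    when the track is stranded.
    """

    track_id: str
    assay: Assay
    strand: Strand
    pair_id: str | None = None

    def __post_init__(self):
        self.assay = Assay(self.assay)
        self.strand = Strand(self.strand)
        if self.strand is Strand.UNSTRANDED:
            if self.pair_id not in (None, ""):
                raise ValueError(f"track {self.track_id}: unstranded tracks take no pair_id")
            self.pair_id = None
        else:
            if not self.pair_id:
                raise ValueError(f"track {self.track_id}: stranded tracks need a pair_id")


def _pair_permutation(meta: Sequence[TrackMeta]) -> np.ndarray:
    """Index permutation exchanging each FWD track with its REV partner.

    Validates that the pairing is a perfect matching; unstranded tracks
    map to themselves.
    """
    perm = np.arange(len(meta))
    by_pair: dict[str, dict[Strand, int]] = {}
    for i, m in enumerate(meta):
        if m.strand is Strand.UNSTRANDED:
            continue
        by_pair.setdefault(m.pair_id, {})
        if m.strand in by_pair[m.pair_id]:
            raise ValueError(f"pair {m.pair_id}: duplicate {m.strand.value} track")
        by_pair[m.pair_id][m.strand] = i
    for pid, members in by_pair.items():
        if set(members) != {Strand.FWD, Strand.REV}:
            raise ValueError(f"pair {pid}: needs exactly one FWD and one REV track")
        f, r = members[Strand.FWD], members[Strand.REV]
        perm[f], perm[r] = r, f
    return perm


@dataclasses.dataclass
class TrackSet:
    """Binned, nonnegative coverage for T tracks over B bins."""

    values: np.ndarray  # (B, T)
    bin_width: int
    meta: list[TrackMeta]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be (bins, tracks)")
        if self.values.shape[1] != len(self.meta):
            raise ValueError(
                f"{self.values.shape[1]} value columns but {len(self.meta)} meta rows")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class DataConfig:
    """Window geometry, transforms, and split bookkeeping.

    Defaults are the full-scale settings: 393,216-bp windows, 32-bp bins,
    2,048 bins cropped from each end before the loss, ±3-nt shift
    augmentation, squash exponent 3/4 with threshold 384, six folds grouped
    4:1:1 into train:validation:test.
    """

    window_len: int = 393_216
    bin_width: int = 32
    crop_bins: int = 2_048
    shift_max: int = 3
    squash_exponent: float = 0.75
    squash_threshold: float = 384.0
    n_folds: int = 6
    split_ratio: tuple[int, int, int] = (4, 1, 1)

    def __post_init__(self):
        if self.window_len % self.bin_width != 0:
            raise ValueError("window_len must be divisible by bin_width")
        if 2 * self.crop_bins >= self.window_len // self.bin_width:
            raise ValueError("crop_bins too large for window")
        if self.squash_threshold <= 0:
            raise ValueError("squash_threshold must be positive")
        if sum(self.split_ratio) != self.n_folds:
            raise ValueError("split_ratio must sum to n_folds")

    @property
    def n_bins(self) -> int:
        return self.window_len // self.bin_width

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DataConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "split_ratio" in kwargs:
            kwargs["split_ratio"] = tuple(kwargs["split_ratio"])
        return cls(**kwargs)


@dataclasses.dataclass
class SplitAssignment:
    """One rotation of the fold → train/val/test grouping."""

    rotation: int
    fold_of_window: np.ndarray  # (n_windows,) fold index per window
    role_of_fold: dict[int, Role]

    def windows_with_role(self, role: Role) -> np.ndarray:
        folds = [f for f, r in self.role_of_fold.items() if r is role]
        return np.flatnonzero(np.isin(self.fold_of_window, folds))


# -------------------------------------------------------------------------
# encoding

def one_hot_encode(seq: str) -> np.ndarray:
    """One-hot encode DNA with columns A,C,G,T; N → all-zero row.

    Case-insensitive; any character outside {A,C,G,T,N} is rejected with
    its position.
    """
    up = seq.upper()
    arr = np.zeros((len(seq), 4), dtype=np.float64)
    for i, ch in enumerate(up):
        if ch == "N":
            continue
        j = _BASE_INDEX.get(ch)
        if j is None:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
        arr[i, j] = 1.0
    return arr


def one_hot_decode(onehot: np.ndarray) -> str:
    out = []
    for row in np.asarray(onehot):
        s = row.sum()
        out.append("N" if s == 0 else BASES[int(row.argmax())])
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_onehot(onehot: np.ndarray) -> np.ndarray:
    """Reverse-complement a one-hot matrix.

    With column order A,C,G,T, complementation is a reversal of the column
    axis, so revcomp is a flip of both axes.  All-zero (N) rows stay
    all-zero.
    """
    return np.ascontiguousarray(onehot[::-1, ::-1])


# -------------------------------------------------------------------------
# coverage transforms

def squash(x, exponent: float = 0.75, threshold: float = 384.0,
           clip_exponent: float | None = None):
    """Monotone invertible compression of coverage.

    Implements ``min(x**exponent, threshold) + max(0, x**exponent −
    threshold)`` exactly as written (the two branches sum back to
    ``x**exponent``).  ``clip_exponent`` optionally soft-clips the
    above-threshold branch by raising it to that power (e.g. 0.5), the
    behaviour used by earlier coverage models; default off.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("squash requires nonnegative input")
    p = x ** exponent
    excess = np.maximum(0.0, p - threshold)
    if clip_exponent is not None:
        excess = excess ** clip_exponent
    return np.minimum(p, threshold) + excess


def unsquash(y, exponent: float = 0.75, threshold: float = 384.0,
             clip_exponent: float | None = None):
    """Inverse of :func:`squash` (elementwise)."""
    y = np.asarray(y, dtype=np.float64)
    if np.any(y < 0):
        raise ValueError("unsquash requires nonnegative input")
    over = y > threshold
    excess = np.where(over, y - threshold, 0.0)
    if clip_exponent is not None:
        excess = excess ** (1.0 / clip_exponent)
    p = np.where(over, threshold + excess, y)
    return p ** (1.0 / exponent)


def bin_coverage(per_base: np.ndarray, bin_width: int) -> np.ndarray:
    """Sum-pool per-base coverage into fixed-width bins.

    Sum pooling keeps the count interpretation the Poisson loss expects;
    total counts are conserved exactly.
    """
    per_base = np.asarray(per_base, dtype=np.float64)
    L = per_base.shape[0]
    if L % bin_width != 0:
        raise ValueError(f"length {L} not divisible by bin width {bin_width}")
    shape = (L // bin_width, bin_width) + per_base.shape[1:]
    return per_base.reshape(shape).sum(axis=1)


def crop_bins(tracks: TrackSet, crop: int) -> TrackSet:
    """Drop ``crop`` bins from each end (loss is computed on the interior)."""
    if crop < 0:
        raise ValueError("crop must be nonnegative")
    if 2 * crop >= tracks.n_bins:
        raise ValueError(f"cropping {crop} bins from each end of {tracks.n_bins} leaves nothing")
    if crop == 0:
        return tracks
    return TrackSet(tracks.values[crop:tracks.n_bins - crop], tracks.bin_width, tracks.meta)


# -------------------------------------------------------------------------
# augmentation

def revcomp_augment(win: SequenceWindow, tracks: TrackSet) -> tuple[SequenceWindow, TrackSet]:
    """Reverse-complement augmentation.

    The sequence is reverse-complemented; every track's bin order is
    reversed; each FWD track additionally exchanges values with its REV
    partner.  Unstranded tracks are reversed in place.  Applying twice is
    the identity.
    """
    perm = _pair_permutation(tracks.meta)
    new_win = SequenceWindow(win.chrom, win.start, revcomp_onehot(win.onehot))
    new_vals = tracks.values[::-1][:, perm]
    return new_win, TrackSet(np.ascontiguousarray(new_vals), tracks.bin_width, tracks.meta)


def shift_augment(win: SequenceWindow, shift: int, shift_max: int = 3) -> SequenceWindow:
    """Translate the one-hot rows by ``shift`` bp, zero-filling vacated rows.

    Output bins are deliberately left untouched by the caller; only the
    input encoding moves.  Positive shift moves the sequence toward higher
    coordinates.
    """
    if abs(shift) > shift_max:
        raise ValueError(f"|shift|={abs(shift)} exceeds shift_max={shift_max}")
    if shift == 0:
        return win
    out = np.zeros_like(win.onehot)
    if shift > 0:
        out[shift:] = win.onehot[:-shift]
    else:
        out[:shift] = win.onehot[-shift:]
    return SequenceWindow(win.chrom, win.start, out)


# -------------------------------------------------------------------------
# splits

def make_splits(n_windows: int, cfg: DataConfig, seed: int) -> list[SplitAssignment]:
    """Assign windows to folds and build the four split rotations.

    Windows are shuffled with the given seed and dealt into ``n_folds``
    contiguous blocks of near-equal size (±1).  Rotation r uses fold r as
    TEST, fold (r+1) mod n_folds as VAL and the rest as TRAIN, so the four
    rotations have pairwise distinct test folds and distinct validation
    folds.
    """
    if n_windows < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} windows, got {n_windows}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_windows)
    fold_of_window = np.empty(n_windows, dtype=np.int64)
    bounds = np.linspace(0, n_windows, cfg.n_folds + 1).round().astype(int)
    for f in range(cfg.n_folds):
        fold_of_window[order[bounds[f]:bounds[f + 1]]] = f
    out = []
    for r in range(4):
        roles = {f: Role.TRAIN for f in range(cfg.n_folds)}
        roles[r % cfg.n_folds] = Role.TEST
        roles[(r + 1) % cfg.n_folds] = Role.VAL
        out.append(SplitAssignment(r, fold_of_window.copy(), roles))
    return out


# -------------------------------------------------------------------------
# file I/O (plain-text formats only)

def write_fasta(path: str | Path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, read_ahead=10_000_000)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def write_bedgraph(path: str | Path, chrom: str, start: int, binned: np.ndarray,
                   bin_width: int) -> None:
    """Write one binned track as BedGraph (one fixed-width interval per bin)."""
    binned = np.asarray(binned)
    with open(path, "w") as fh:
        for i, v in enumerate(binned):
            s = start + i * bin_width
            fh.write(f"{chrom}\t{s}\t{s + bin_width}\t{v:.10g}\n")


def read_bedgraph(path: str | Path, chrom: str, start: int, length: int) -> np.ndarray:
    """Read BedGraph intervals overlapping [start, start+length) on ``chrom``
    into a per-base vector (value assigned to every bp of the interval)."""
    per_base = np.zeros(length, dtype=np.float64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed BedGraph record")
            try:
                c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BedGraph record") from exc
            if c != chrom or e <= start or s >= start + length:
                continue
            lo = max(s, start) - start
            hi = min(e, start + length) - start
            per_base[lo:hi] += v
    return per_base


def write_track_meta(path: str | Path, meta: Sequence[TrackMeta]) -> None:
    df = pd.DataFrame(
        {
            "track_id": [m.track_id for m in meta],
            "assay": [m.assay.value for m in meta],
            "strand": [m.strand.value for m in meta],
            "pair_id": [m.pair_id or "" for m in meta],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_track_meta(path: str | Path) -> list[TrackMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        TrackMeta(r.track_id, Assay(r.assay), Strand(r.strand), r.pair_id or None)
        for r in df.itertuples()
    ]


def write_track_matrix(path: str | Path, tracks: TrackSet, window_id: str) -> None:
    """Binned coverage matrix as TSV: one row per bin, one column per track."""
    df = pd.DataFrame(tracks.values, columns=[m.track_id for m in tracks.meta])
    df.insert(0, "window", window_id)
    df.insert(1, "bin", np.arange(tracks.n_bins))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_track_matrix(path: str | Path, meta: Sequence[TrackMeta],
                      bin_width: int) -> dict[str, TrackSet]:
    df = pd.read_csv(path, sep="\t")
    cols = [m.track_id for m in meta]
    out = {}
    for wid, grp in df.groupby("window", sort=False):
        grp = grp.sort_values("bin")
        out[str(wid)] = TrackSet(grp[cols].to_numpy(float), bin_width, list(meta))
    return out


def write_vcf(path: str | Path, variants: Iterable[tuple[str, int, str, str, str]],
              contigs: dict[str, int] | None = None) -> None:
    """Write biallelic SNVs.  ``variants``: (chrom, pos0, vid, ref, alt),
    position 0-based (converted to VCF's 1-based on output).  ``contigs``
    optionally maps chromosome names to lengths for the header."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, vid, ref, alt in variants:
            fh.write(f"{chrom}\t{pos0 + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\n")


def read_vcf(path: str | Path) -> list[tuple[str, int, str, str, str]]:
    """Parse a VCF for (chrom, pos0, id, ref, alt) of biallelic SNVs.

    Symbolic and multi-allelic ALT alleles and indels are out of scope and
    rejected with the offending record number.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf.fetch() if vf.index else vf, 1):
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ValueError(f"{path}: record {i} ({rec.chrom}:{rec.pos}): "
                                 "multi-allelic records are not supported")
            alt = alts[0]
            if alt.startswith("<") or len(rec.ref) != 1 or len(alt) != 1:
                raise ValueError(f"{path}: record {i} ({rec.chrom}:{rec.pos}): "
                                 "only single-base substitutions are supported")
            out.append((rec.chrom, rec.pos - 1, rec.id or f"var{i}", rec.ref, alt))
    return out
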