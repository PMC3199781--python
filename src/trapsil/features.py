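"""Genomic feature tracks: I/O, windowed quantification, anchored profiles.

Tracks come in four kinds:

* ``interval``  — BED intervals (CpG islands, DNase I hypersensitive sites);
* ``point_count`` — SGA-format counted points (ChIP-seq read 5' positions);
* ``sequence_gc`` / ``sequence_cpg`` — derived from the genome sequence
  (G+C base fraction, CG-dinucleotide frequency);
* ``tss_set`` — a point set of transcription starts (gene density and
  expression-threshold features count qualifying TSSs in a window).

SGA is a 5-column tab-separated text format: chrom, feature name, position
(1-based in the file, converted to 0-based on load), strand (+/-/0), count.
Windows are half-open ``[anchor - half_width, anchor + half_width)`` clipped
at chromosome ends; no wraparound.  Point counts are capped per position at
a cutoff (default 1, i.e. occupied positions are counted once) — the
convention used by ChIPcor-style aggregation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINDS = ("interval", "point_count", "sequence_gc", "sequence_cpg", "tss_set")

# Interval half-width ladder: 0.1 kb to 10 Mb; the reduced ladder (1 kb to
# 1 Mb) is used for gene-group level scans.
DEFAULT_SCALES = (100, 1_000, 10_000, 100_000, 1_000_000, 10_000_000)
REDUCED_SCALES = (1_000, 10_000, 100_000, 1_000_000)


@dataclass(frozen=True)
class IntervalScale:
    half_width: int

    @property
    def label(self) -> str:
        hw = self.half_width
        if hw % 1_000_000 == 0:
            return f"{hw // 1_000_000}Mb"
        if hw % 1_000 == 0:
            return f"{hw // 1_000}kb"
        return f"{hw / 1_000:g}kb"


@dataclass
class FeatureTrack:
    """One named genomic feature with quantification semantics."""

    name: str
    kind: str
    # interval: chrom -> (starts_sorted, ends_sorted_by_start, ends_sorted)
    # point_count: chrom -> (positions_sorted, counts, strands)
    # tss_set: chrom -> positions_sorted
    data: dict = field(default_factory=dict)
    sequences: dict | None = None  # genome, for sequence_* kinds

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")


def interval_track(name: str, intervals: dict[str, list[tuple[int, int]]]) -> FeatureTrack:
    data = {}
    for chrom, ivs in intervals.items():
        ivs = sorted(ivs)
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        data[chrom] = (starts, ends, np.sort(ends))
    return FeatureTrack(name, "interval", data)


def point_track(
    name: str, points: dict[str, list[tuple[int, int]]], strands: dict | None = None
) -> FeatureTrack:
    """Counted points per chromosome; ``points[chrom] = [(pos0based, count)]``."""
    data = {}
    for chrom, pts in points.items():
        order = sorted(range(len(pts)), key=lambda i: pts[i][0])
        pos = np.array([pts[i][0] for i in order], dtype=np.int64)
        cnt = np.array([pts[i][1] for i in order], dtype=np.int64)
        if (cnt < 0).any():
            raise ValueError(f"track {name}: negative count")
        strnd = np.array(
            [strands[chrom][i] for i in order] if strands else ["0"] * len(pts)
        )
        data[chrom] = (pos, cnt, strnd)
    return FeatureTrack(name, "point_count", data)


def tss_track(name: str, positions: dict[str, list[int]]) -> FeatureTrack:
    return FeatureTrack(
        name, "tss_set",
        {c: np.array(sorted(p), dtype=np.int64) for c, p in positions.items()},
    )


def sequence_track(name: str, sequences: dict[str, str], kind: str) -> FeatureTrack:
    if kind not in ("sequence_gc", "sequence_cpg"):
        raise ValueError(kind)
    return FeatureTrack(name, kind, {}, sequences=sequences)


# ---------------------------------------------------------------------------
# SGA / BED / expression I/O
# ---------------------------------------------------------------------------

def read_sga(path, name: str | None = None) -> FeatureTrack:
    """Load an SGA file (1-based positions converted to 0-based)."""
    points: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, list[str]] = {}
    feat_name = name
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: SGA needs 5 columns, got {len(parts)}")
            chrom, fname, pos_s, strand, cnt_s = parts
            if strand not in "+-0":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                pos, cnt = int(pos_s), int(cnt_s)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer position/count") from e
            feat_name = feat_name or fname
            points.setdefault(chrom, []).append((pos - 1, cnt))
            strands.setdefault(chrom, []).append(strand)
    return point_track(feat_name or "feature", points, strands)


def write_sga(track: FeatureTrack, path) -> None:
    if track.kind != "point_count":
        raise ValueError("write_sga requires a point_count track")
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            pos, cnt, strnd = track.data[chrom]
            for p, c, s in zip(pos, cnt, strnd):
                fh.write(f"{chrom}\t{track.name}\t{p + 1}\t{s}\t{c}\n")


def read_bed(path, name: str | None = None) -> FeatureTrack:
    """BED3/BED6 reader (0-based half-open, native BED convention)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            intervals.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return interval_track(name or str(path), intervals)


def write_bed(track: FeatureTrack, path) -> None:
    if track.kind != "interval":
        raise ValueError("write_bed requires an interval track")
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, _ = track.data[chrom]
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_expression(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))


def write_expression(expr: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tscore\n")
        for g in sorted(expr):
            fh.write(f"{g}\t{expr[g]:.6g}\n")


def expression_threshold_tss(
    clusters, expression: dict[str, float], top_fraction: float, name: str
) -> FeatureTrack:
    """TSS set of genes in the top ``top_fraction`` of the expression table,
    rank-based with ties broken by gene id (deterministic)."""
    ranked = sorted(expression, key=lambda g: (-expression[g], g))
    n_keep = max(1, int(math.floor(len(ranked) * top_fraction)))
    keep = set(ranked[:n_keep])
    positions: dict[str, list[int]] = {}
    for c in clusters:
        if c.cluster_id in keep:
            positions.setdefault(c.chrom, []).append(c.tss)
    return tss_track(name, positions)


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def _chrom_length(track: FeatureTrack, chrom: str) -> int | None:
    if track.sequences is not None and chrom in track.sequences:
        return len(track.sequences[chrom])
    return None


def window_value(
    track: FeatureTrack, chrom: str, win_start: int, win_end: int,
    cutoff: float | None = 1,
) -> float:
    """Feature amount in the half-open window [win_start, win_end).

    interval: number of overlapping intervals; point_count: sum of per-
    position counts capped at cutoff (cutoff=None means no cap); sequence_gc:
    G/C base fraction; sequence_cpg: CG dinucleotide frequency; tss_set:
    number of member positions inside the window.
    """
    if win_end <= win_start:
        return 0.0
    if track.kind == "interval":
        entry = track.data.get(chrom)
        if entry is None:
            return 0.0
        starts, _, ends_sorted = entry
        n = len(starts)
        n_start_after = n - int(np.searchsorted(starts, win_end, side="left"))
        n_end_before = int(np.searchsorted(ends_sorted, win_start, side="right"))
        return float(n - n_start_after - n_end_before)
    if track.kind == "point_count":
        entry = track.data.get(chrom)
        if entry is None:
            return 0.0
        pos, cnt, _ = entry
        lo = int(np.searchsorted(pos, win_start, side="left"))
        hi = int(np.searchsorted(pos, win_end, side="left"))
        sel = cnt[lo:hi]
        if cutoff is not None:
            sel = np.minimum(sel, cutoff)
        return float(sel.sum())
    if track.kind == "tss_set":
        pos = track.data.get(chrom)
        if pos is None:
            return 0.0
        return float(np.searchsorted(pos, win_end, side="left")
                     - np.searchsorted(pos, win_start, side="left"))
    seq = track.sequences[chrom]
    sub = seq[max(0, win_start) : win_end].upper()
    if not sub:
        return 0.0
    if track.kind == "sequence_gc":
        return (sub.count("G") + sub.count("C")) / len(sub)
    # CG dinucleotide frequency per bp of window
    return sub.count("CG") / len(sub)


def quantify(
    track: FeatureTrack, chrom: str, anchor: int, scale: IntervalScale | int,
    chrom_length: int | None = None, cutoff: float | None = 1,
) -> float:
    """Feature amount around an anchor at one interval scale.

    The window is [anchor - half_width, anchor + half_width) clipped to the
    chromosome; values are raw (not end-corrected) — matched controls absorb
    edge bias.
    """
    hw = scale.half_width if isinstance(scale, IntervalScale) else int(scale)
    if chrom_length is None:
        chrom_length = _chrom_length(track, chrom)
    if chrom_length is not None and not (0 <= anchor < chrom_length):
        raise ValueError(f"anchor {anchor} outside {chrom} (length {chrom_length})")
    ws = max(0, anchor - hw)
    we = anchor + hw
    if chrom_length is not None:
        we = min(we, chrom_length)
    return window_value(track, chrom, ws, we, cutoff=cutoff)


def distance_to_nearest(anchor: int, positions: np.ndarray) -> float:
    """Minimum absolute distance from anchor to a sorted position set; ties
    resolve to the smaller coordinate (same distance either way).  NaN when
    the set is empty."""
    positions = np.asarray(positions)
    if positions.size == 0:
        return float("nan")
    i = int(np.searchsorted(positions, anchor))
    best = math.inf
    if i < positions.size:
        best = abs(int(positions[i]) - anchor)
    if i > 0:
        best = min(best, abs(anchor - int(positions[i - 1])))
    return float(best)


# ---------------------------------------------------------------------------
# Anchored (ChIPcor-style) and metagene profiles
# ---------------------------------------------------------------------------

def anchored_profile(
    track: FeatureTrack,
    anchors: list[tuple[str, int, str]],
    range_bp: int = 40_000,
    window: int = 500,
    cutoff: float | None = 1,
) -> np.ndarray:
    """Aggregate feature counts in fixed bins around oriented anchors.

    Offsets run over [-range_bp, +range_bp); bin b covers
    [-range_bp + b*window, -range_bp + (b+1)*window) in anchor-oriented
    coordinates (minus-strand anchors flip the axis so bin 0 is always the
    most 5'-distal).  Point counts are capped per position at ``cutoff``.
    Only point_count and tss_set tracks are meaningful targets here.
    """
    if (2 * range_bp) % window != 0:
        raise ValueError("2*range_bp must be divisible by window")
    n_bins = 2 * range_bp // window
    out = np.zeros(n_bins, dtype=float)
    for chrom, pos, strand in anchors:
        if track.kind == "point_count":
            p, c, _ = track.data.get(chrom, (np.array([], dtype=np.int64),) * 3)
        elif track.kind == "tss_set":
            p = track.data.get(chrom, np.array([], dtype=np.int64))
            c = np.ones_like(p)
        else:
            raise ValueError("anchored_profile supports point_count/tss_set tracks")
        lo = int(np.searchsorted(p, pos - range_bp, side="left"))
        hi = int(np.searchsorted(p, pos + range_bp + 1, side="left"))
        for pp, cc in zip(p[lo:hi], c[lo:hi]):
            offset = int(pp) - pos if strand != "-" else pos - int(pp)
            if -range_bp <= offset < range_bp:
                val = min(cc, cutoff) if cutoff is not None else cc
                out[(offset + range_bp) // window] += val
    return out


def metagene_profile(
    track: FeatureTrack,
    clusters,
    n_bins: int = 40,
    flank: int = 2_000,
    flank_bin: int = 50,
    cutoff: float | None = 1,
) -> tuple[np.ndarray, list]:
    """Per-gene feature densities over length-normalized gene bodies.

    Each gene body is split into ``n_bins`` equal-width bins (the last bin
    absorbs the division remainder); flanks of ``flank`` bp on both sides are
    binned at a fixed ``flank_bin`` width.  Rows are strand-flipped so column
    0 is always the 5' flank end.  Values are per-bp densities of capped
    counts.  Genes shorter than ``n_bins`` bp are skipped with a warning.

    Returns (matrix genes x (flank bins + n_bins + flank bins), kept clusters).
    """
    if flank % flank_bin != 0:
        raise ValueError("flank must be divisible by flank_bin")
    nf = flank // flank_bin
    rows, kept = [], []
    for c in clusters:
        if c.size < n_bins:
            warnings.warn(f"gene {c.cluster_id} shorter than {n_bins} bp; skipped")
            continue
        body_w = c.size // n_bins
        edges = [c.start + i * body_w for i in range(n_bins)] + [c.end]
        up = [(c.start - flank + i * flank_bin, c.start - flank + (i + 1) * flank_bin)
              for i in range(nf)]
        down = [(c.end + i * flank_bin, c.end + (i + 1) * flank_bin) for i in range(nf)]
        body = [(edges[i], edges[i + 1]) for i in range(n_bins)]
        bins = up + body + down
        dens = [
            window_value(track, c.chrom, max(0, ws), we, cutoff=cutoff) / (we - ws)
            for ws, we in bins
        ]
        if c.strand == "-":
            dens = dens[::-1]
        rows.append(dens)
        kept.append(c)
    return np.array(rows, dtype=float), kept
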