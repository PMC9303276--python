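"""Sequence- and track-based features around origins.

GC content, GC/AT skew profiles centred on origins, deepTools-style scaled
coverage matrices, genome GC-decile fractions, and assembly of the per-origin
feature table used by the efficiency model.

Genome sequence arguments accept either a ``dict[str, str]`` or a
``pyfaidx.Fasta`` handle (anything where ``genome[chrom][a:b]`` yields
sequence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import OriginCall
from .genome import GenomeLayout, Interval, SignalTrack

logger = logging.getLogger(__name__)

_G, _C, _A, _T = (ord(b) for b in "GCAT")


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    start = max(start, 0)
    seq = genome[chrom][start:end]
    return str(seq).upper()


def _seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def gc_content(sequence: str) -> float:
    """(G + C) / (A + C + G + T); N bases are excluded. NaN when no informative base."""
    codes = _seq_to_codes(sequence)
    gc = int(((codes == _G) | (codes == _C)).sum())
    at = int(((codes == _A) | (codes == _T)).sum())
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


@dataclass
class SkewProfile:
    """Mean per-bin composition skew around origin centres.

    ``values[i]`` is the mean skew across origins in the bin at
    ``offsets[i]`` bp from the centre; ``informative[i]`` counts the origins
    with at least one informative base in that bin (bins with none contribute
    0 and are flagged when no origin informs them).
    """

    offsets: np.ndarray
    values: np.ndarray
    informative: np.ndarray
    kind: str
    bin_size: int
    window: int


def skew_profile(
    origins: list[OriginCall] | list[Interval],
    genome,
    kind: str = "GC",
    bin_size: int = 100,
    window: int = 20_000,
) -> SkewProfile:
    """GC skew (G-C)/(G+C) (or AT skew (A-T)/(A+T)) in bins around origin centres.

    Computed on the reference (plus) strand, per origin, then averaged across
    origins aligned at their centres.
    """
    if kind not in ("GC", "AT"):
        raise ValueError("kind must be 'GC' or 'AT'")
    if window % bin_size:
        raise ValueError("bin_size must divide window")
    pos_base, neg_base = (_G, _C) if kind == "GC" else (_A, _T)
    n_bins = window // bin_size
    half = window // 2
    offsets = np.arange(n_bins) * bin_size - half + bin_size // 2
    total = np.zeros(n_bins)
    informative = np.zeros(n_bins, dtype=np.int64)
    for o in origins:
        centre = (o.start + o.end) // 2
        seq = _fetch(genome, o.chrom, centre - half, centre + half)
        codes = _seq_to_codes(seq)
        if codes.size < window:  # chromosome edge: pad with N (uninformative)
            pad = np.full(window, ord("N"), dtype=np.uint8)
            lo = max(0, half - centre)
            pad[lo:lo + codes.size] = codes
            codes = pad
        pos = (codes == pos_base).reshape(n_bins, bin_size).sum(axis=1)
        neg = (codes == neg_base).reshape(n_bins, bin_size).sum(axis=1)
        denom = pos + neg
        ok = denom > 0
        skew = np.zeros(n_bins)
        skew[ok] = (pos[ok] - neg[ok]) / denom[ok]
        total += skew
        informative += ok
    values = total / max(len(list(origins)), 1)
    return SkewProfile(offsets, values, informative, kind, bin_size, window)


@dataclass
class CoverageMatrix:
    """Regions x bins matrix of mean signal (scale-regions semantics).

    Each region body is linearly rescaled to a common ``body`` length; flanks
    are binned at fixed width. ``truncated`` flags bins that fall outside the
    chromosome at region edges.
    """

    matrix: np.ndarray
    truncated: np.ndarray
    bin_size: int
    body: int
    flank: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.bin_size

    @property
    def n_body_bins(self) -> int:
        return self.body // self.bin_size


def scaled_signal_matrix(
    regions: list[Interval] | list[OriginCall],
    track: SignalTrack,
    layout: GenomeLayout,
    bin_size: int = 10,
    body: int = 5_000,
    flank: int = 10_000,
) -> CoverageMatrix:
    """Mean track signal in fixed-width flank bins and scaled body bins.

    The body of each region is mapped linearly onto ``body / bin_size``
    destination bins; each destination bin takes the length-weighted mean of
    the track over its source span. Uncovered bp contribute 0.
    """
    if body % bin_size or flank % bin_size:
        raise ValueError("bin_size must divide body and flank")
    n_fb, n_bb = flank // bin_size, body // bin_size
    n_cols = 2 * n_fb + n_bb
    mat = np.zeros((len(regions), n_cols))
    truncated = np.zeros((len(regions), n_cols), dtype=bool)
    for r, region in enumerate(regions):
        chrom = region.chrom
        L = layout.length_of(chrom)
        # left flank
        for j in range(n_fb):
            a = region.start - flank + j * bin_size
            b = a + bin_size
            if a < 0:
                truncated[r, j] = True
                a = max(a, 0)
            if b <= 0:
                continue
            mat[r, j] = track.mean_over(chrom, a, b)
        # scaled body
        span = region.end - region.start
        for j in range(n_bb):
            a = region.start + span * j / n_bb
            b = region.start + span * (j + 1) / n_bb
            mat[r, n_fb + j] = track.mean_over(chrom, a, b)
        # right flank
        for j in range(n_fb):
            a = region.end + j * bin_size
            b = a + bin_size
            if b > L:
                truncated[r, n_fb + n_bb + j] = True
                b = min(b, L)
            if a >= L:
                continue
            mat[r, n_fb + n_bb + j] = track.mean_over(chrom, a, b)
    return CoverageMatrix(mat, truncated, bin_size, body, flank)


def genome_gc_windows(genome, layout: GenomeLayout, window: int = 50):
    """GC fraction of consecutive fixed windows over the whole genome.

    Returns ``(gc, index)`` where ``index`` maps (chrom, window ordinal) to a
    row; all-N windows carry NaN.
    """
    gcs = []
    index: dict[str, tuple[int, int]] = {}
    row = 0
    for chrom, L in layout.chromosomes:
        codes = _seq_to_codes(_fetch(genome, chrom, 0, L))
        n_win = -(-L // window)
        padded = np.full(n_win * window, ord("N"), dtype=np.uint8)
        padded[:codes.size] = codes
        win = padded.reshape(n_win, window)
        gc = ((win == _G) | (win == _C)).sum(axis=1).astype(float)
        at = ((win == _A) | (win == _T)).sum(axis=1).astype(float)
        denom = gc + at
        vals = np.where(denom > 0, gc / np.where(denom > 0, denom, 1), np.nan)
        gcs.append(vals)
        index[chrom] = (row, row + n_win)
        row += n_win
    return np.concatenate(gcs), index


@dataclass
class DecileFractions:
    fractions: np.ndarray  # length 10, sums to 1
    boundaries: np.ndarray  # the 9 decile cut points of genome GC
    degenerate: bool  # True when the genome GC distribution has tied deciles


def gc_decile_fractions(
    intervals: list[Interval] | list[OriginCall],
    genome,
    layout: GenomeLayout,
    window: int = 50,
) -> DecileFractions:
    """Fraction of query intervals falling in each genome-wide GC decile.

    The genome is segmented into fixed windows (default 50 bp); decile
    boundaries come from the genome-wide GC distribution; each interval is
    assigned by the decile of the window containing its midpoint.
    """
    gc, index = genome_gc_windows(genome, layout, window)
    finite = gc[np.isfinite(gc)]
    if finite.size == 0:
        raise ValueError("genome has no informative windows")
    boundaries = np.quantile(finite, np.arange(1, 10) / 10)
    degenerate = bool(len(np.unique(boundaries)) < 9)
    if degenerate:
        logger.warning("tied GC decile boundaries (near-uniform genome composition)")
    counts = np.zeros(10, dtype=np.int64)
    for iv in intervals:
        mid = (iv.start + iv.end) // 2
        lo, _hi = index[iv.chrom]
        val = gc[lo + mid // window]
        if not np.isfinite(val):
            continue
        d = int(np.searchsorted(boundaries, val, "right"))
        counts[d] += 1
    total = counts.sum()
    fractions = counts / total if total else counts.astype(float)
    return DecileFractions(fractions, boundaries, degenerate)


def assemble_feature_table(
    origins: list[OriginCall],
    tracks: dict[str, SignalTrack] | None = None,
    genome=None,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """One row per origin: efficiency (response) plus per-feature mean signal.

    Track features are the length-weighted mean of the track over the origin
    interval; with a genome, a ``gc`` column (GC content of the origin
    sequence) is added. Tracks missing an origin's chromosome contribute 0
    (warned once per track).
    """
    tracks = tracks or {}
    if not tracks and genome is None:
        raise ValueError("need at least one track or a genome sequence")
    data: dict[str, list[float]] = {"efficiency": [o.efficiency for o in origins]}
    for name, track in tracks.items():
        missing = {o.chrom for o in origins} - set(track.chromosomes)
        if missing:
            logger.warning("track %r missing chromosome(s) %s; zeros used", name, sorted(missing))
        data[name] = [track.mean_over(o.chrom, o.start, o.end) for o in origins]
    if genome is not None:
        data["gc"] = [gc_content(_fetch(genome, o.chrom, o.start, o.end)) for o in origins]
    df = pd.DataFrame(data, index=[o.name or f"origin_{i+1}" for i, o in enumerate(origins)])
    return df
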