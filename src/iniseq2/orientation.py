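"""Transcriptional orientation of genes around origins.

Classes the first gene on either side of each origin midpoint as convergent,
divergent or co-oriented, profiles stranded gene-body coverage around origins
by efficiency class, and draws the equidistant-position randomized control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .caller import OriginCall
from .genome import GeneRecord

logger = logging.getLogger(__name__)

ORIENTATION_LABELS = ("convergent", "divergent", "co-oriented", "unflanked")


@dataclass
class OrientationCall:
    origin: OriginCall
    upstream: GeneRecord | None
    downstream: GeneRecord | None
    label: str


def flanking_gene_orientation(
    origin: OriginCall, genes: list[GeneRecord]
) -> OrientationCall:
    """Class the orientation of the first gene wholly on either side of the origin midpoint.

    divergent = (upstream -, downstream +); convergent = (upstream +,
    downstream -); co-oriented = equal strands; unflanked when a side has no
    gene. Genes overlapping the midpoint are skipped.
    """
    mid = origin.midpoint
    upstream: GeneRecord | None = None
    downstream: GeneRecord | None = None
    n_skipped = 0
    for g in genes:
        if g.chrom != origin.chrom:
            continue
        if g.end <= mid:
            if upstream is None or g.end > upstream.end:
                upstream = g
        elif g.start >= mid:
            if downstream is None or g.start < downstream.start:
                downstream = g
        else:
            n_skipped += 1
    if n_skipped:
        logger.info(
            "%d gene(s) overlapping the midpoint of %s:%d-%d were skipped",
            n_skipped, origin.chrom, origin.start, origin.end,
        )
    if upstream is None or downstream is None:
        return OrientationCall(origin, upstream, downstream, "unflanked")
    if upstream.strand == downstream.strand:
        label = "co-oriented"
    elif (upstream.strand, downstream.strand) == ("-", "+"):
        label = "divergent"
    else:
        label = "convergent"
    return OrientationCall(origin, upstream, downstream, label)


def orientation_fractions(calls: list[OrientationCall]) -> dict[str, float]:
    """Fractions of convergent/divergent/co-oriented over flanked origins."""
    flanked = [c for c in calls if c.label != "unflanked"]
    if not flanked:
        return {lab: float("nan") for lab in ORIENTATION_LABELS[:3]}
    return {
        lab: sum(c.label == lab for c in flanked) / len(flanked)
        for lab in ORIENTATION_LABELS[:3]
    }


def orientation_profile(
    origins: list[OriginCall],
    genes: list[GeneRecord],
    half_window: int = 100_000,
    bin_size: int = 1_000,
) -> dict[str | None, dict[str, np.ndarray]]:
    """Per-class stranded gene-body coverage around origin midpoints.

    For each bin offset from the midpoint, the fraction of bin bp covered by
    + and - gene bodies, averaged over the origins of each class. Keys are
    class labels; values are ``{"plus": ..., "minus": ..., "offsets": ...}``.
    """
    if (2 * half_window) % bin_size:
        raise ValueError("bin_size must divide 2 * half_window")
    n_bins = 2 * half_window // bin_size
    offsets = np.arange(n_bins) * bin_size - half_window
    labels = sorted({o.class_label for o in origins}, key=str)
    acc = {lab: {"+": np.zeros(n_bins), "-": np.zeros(n_bins)} for lab in labels}
    counts = {lab: 0 for lab in labels}
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    bin_edges = np.arange(n_bins + 1) * bin_size  # window-relative
    for o in origins:
        counts[o.class_label] += 1
        w_start = o.midpoint - half_window
        for g in genes_by_chrom.get(o.chrom, ()):
            lo = max(g.start, w_start) - w_start
            hi = min(g.end, o.midpoint + half_window) - w_start
            if hi <= lo:
                continue
            overlap = np.clip(np.minimum(bin_edges[1:], hi) - np.maximum(bin_edges[:-1], lo), 0, None)
            acc[o.class_label][g.strand] += overlap
    out: dict[str | None, dict[str, np.ndarray]] = {}
    for lab in labels:
        n = max(counts[lab], 1)
        out[lab] = {
            "plus": acc[lab]["+"] / (n * bin_size),
            "minus": acc[lab]["-"] / (n * bin_size),
            "offsets": offsets,
        }
    return out


def sample_equidistant_controls(
    origins: list[OriginCall], n: int = 8_000, seed: int = 0
) -> list[tuple[str, int]]:
    """Random positions equidistant from two consecutive origins.

    The pool is the midpoint between consecutive origin midpoints on each
    chromosome (odd gaps round down). ``n`` positions are drawn uniformly
    without replacement when the pool is large enough, otherwise with
    replacement (logged).
    """
    by_chrom: dict[str, list[int]] = {}
    for o in sorted(origins, key=lambda o: (o.chrom, o.start)):
        by_chrom.setdefault(o.chrom, []).append(o.midpoint)
    pool: list[tuple[str, int]] = []
    for chrom, mids in by_chrom.items():
        for a, b in zip(mids, mids[1:]):
            pool.append((chrom, (a + b) // 2))
    if not pool:
        raise ValueError("no pair of consecutive origins on any chromosome")
    rng = np.random.default_rng(seed)
    if len(pool) >= n:
        idx = rng.choice(len(pool), size=n, replace=False)
    else:
        logger.info("equidistant pool (%d) smaller than n=%d; sampling with replacement",
                    len(pool), n)
        idx = rng.choice(len(pool), size=n, replace=True)
    return [pool[i] for i in idx]
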