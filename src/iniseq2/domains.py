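"""Higher-order organisation of called origins.

Ini-domains (merge at <= 100 kb, keep >= 6 members), per-class origin
clusters (gap <= 30 kb), inter-origin distances, tolerance-based interval
overlap, the permutation overlap test, and scaled origin-density profiles
over domains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .caller import OriginCall
from .genome import GenomeLayout, Interval

logger = logging.getLogger(__name__)


@dataclass
class IniDomain:
    """A merged run of >= ``min_origins`` origins (gaps <= ``max_gap``)."""

    chrom: str
    start: int
    end: int
    n_origins: int
    n_high: int = 0
    n_medium: int = 0
    n_low: int = 0

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass
class OriginCluster:
    chrom: str
    start: int
    end: int
    n_members: int
    class_label: str | None = None

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


def _tally(members: list[OriginCall]) -> tuple[int, int, int]:
    labels = [o.class_label for o in members]
    return labels.count("high"), labels.count("medium"), labels.count("low")


def build_ini_domains(
    origins: list[OriginCall], max_gap: int = 100_000, min_origins: int = 6
) -> list[IniDomain]:
    """Merge origins whose inter-interval gap is <= ``max_gap`` (transitively).

    A domain spans from its first member's start to its last member's end;
    runs with fewer than ``min_origins`` members are discarded.
    """
    domains: list[IniDomain] = []
    by_chrom: dict[str, list[OriginCall]] = {}
    for o in sorted(origins, key=lambda o: (o.chrom, o.start, o.end)):
        by_chrom.setdefault(o.chrom, []).append(o)
    for chrom, members in by_chrom.items():
        run = [members[0]]
        for o in members[1:]:
            if o.start - run[-1].end <= max_gap:
                run.append(o)
            else:
                if len(run) >= min_origins:
                    h, m, l = _tally(run)
                    domains.append(IniDomain(chrom, run[0].start, run[-1].end, len(run), h, m, l))
                run = [o]
        if len(run) >= min_origins:
            h, m, l = _tally(run)
            domains.append(IniDomain(chrom, run[0].start, run[-1].end, len(run), h, m, l))
    return sorted(domains, key=lambda d: (d.chrom, d.start))


def cluster_origins(
    origins: list[OriginCall], cluster_dist: int = 30_000, min_members: int = 2
) -> list[OriginCluster]:
    """Maximal runs of consecutive origins (of one class) with gap <= ``cluster_dist``."""
    labels = {o.class_label for o in origins}
    if len(labels) > 1:
        raise ValueError(f"cluster_origins expects origins of a single class, got {labels}")
    label = labels.pop() if labels else None
    clusters: list[OriginCluster] = []
    by_chrom: dict[str, list[OriginCall]] = {}
    for o in sorted(origins, key=lambda o: (o.chrom, o.start, o.end)):
        by_chrom.setdefault(o.chrom, []).append(o)
    for chrom, members in by_chrom.items():
        run = [members[0]]
        for o in members[1:]:
            if o.start - run[-1].end <= cluster_dist:
                run.append(o)
            else:
                if len(run) >= min_members:
                    clusters.append(OriginCluster(chrom, run[0].start, run[-1].end, len(run), label))
                run = [o]
        if len(run) >= min_members:
            clusters.append(OriginCluster(chrom, run[0].start, run[-1].end, len(run), label))
    return sorted(clusters, key=lambda c: (c.chrom, c.start))


def inter_origin_distances(
    origins: list[OriginCall], class_label: str | None = None
) -> np.ndarray:
    """Midpoint-to-midpoint distances between consecutive same-class origins.

    Chromosomes with fewer than two qualifying origins contribute nothing.
    """
    if class_label is not None:
        origins = [o for o in origins if o.class_label == class_label]
    by_chrom: dict[str, list[int]] = {}
    for o in sorted(origins, key=lambda o: (o.chrom, o.start)):
        by_chrom.setdefault(o.chrom, []).append(o.midpoint)
    dists: list[int] = []
    for mids in by_chrom.values():
        if len(mids) >= 2:
            dists.extend(np.diff(mids).tolist())
    if not dists:
        logger.info("no chromosome carries two origins of class %r", class_label)
    return np.asarray(dists, dtype=np.int64)


def summarize_distances(dists: np.ndarray) -> dict[str, float]:
    """Median and interquartile range of a distance sample."""
    if dists.size == 0:
        return {"n": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.percentile(dists, [25, 50, 75])
    return {"n": int(dists.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


@dataclass
class OverlapResult:
    """Venn-style overlap counts between two interval sets at a gap tolerance.

    ``n_intersect`` counts A intervals with at least one B interval within
    ``max_dist``; ``n_A_only + n_intersect == |A|``. ``n_B_only`` counts B
    intervals with no A interval within the tolerance.
    """

    n_A_only: int
    n_B_only: int
    n_intersect: int
    max_dist: int


def _as_arrays(intervals: list[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (
            np.array([s for s, _ in pairs], dtype=np.int64),
            np.array([e for _, e in pairs], dtype=np.int64),
        )
    return out


def _hits(
    q_starts: np.ndarray, q_ends: np.ndarray,
    t_starts: np.ndarray, t_ends: np.ndarray, max_dist: int,
) -> np.ndarray:
    """Boolean: for each query interval, does any target lie within ``max_dist``?

    The gap between overlapping or touching intervals is 0; otherwise it is
    the bp separation. Targets must be sorted by start.
    """
    cummax_end = np.maximum.accumulate(t_ends)
    idx = np.searchsorted(t_starts, q_ends + max_dist, "right")
    hit = np.zeros(q_starts.size, dtype=bool)
    nz = idx > 0
    hit[nz] = cummax_end[idx[nz] - 1] >= q_starts[nz] - max_dist
    return hit


def intersect_with_tolerance(
    A: list[Interval], B: list[Interval], max_dist: int = 0
) -> OverlapResult:
    """Count A/B intervals that lie within ``max_dist`` bp of the other set.

    Each interval is counted once no matter how many partners it hits
    (Venn-diagram semantics).
    """
    a_arr, b_arr = _as_arrays(A), _as_arrays(B)
    n_a_hit = n_b_hit = 0
    for chrom, (qs, qe) in a_arr.items():
        if chrom in b_arr:
            ts, te = b_arr[chrom]
            n_a_hit += int(_hits(qs, qe, ts, te, max_dist).sum())
    for chrom, (qs, qe) in b_arr.items():
        if chrom in a_arr:
            ts, te = a_arr[chrom]
            n_b_hit += int(_hits(qs, qe, ts, te, max_dist).sum())
    return OverlapResult(
        n_A_only=len(A) - n_a_hit,
        n_B_only=len(B) - n_b_hit,
        n_intersect=n_a_hit,
        max_dist=max_dist,
    )


@dataclass
class PermutationResult:
    observed: float
    permuted_mean: float
    permuted_sd: float
    z: float
    p: float
    n_perm: int


def _random_placement(
    lengths: np.ndarray, chrom_len: int, n_perm: int, rng: np.random.Generator,
    max_tries: int = 100,
) -> np.ndarray:
    """(n_perm, n) start coordinates: uniform per interval, self-overlap avoided by rejection."""
    n = lengths.size
    starts = rng.integers(0, chrom_len - lengths + 1, size=(n_perm, n))
    for _ in range(max_tries):
        order = np.argsort(starts, axis=1, kind="stable")
        s_sorted = np.take_along_axis(starts, order, axis=1)
        l_sorted = lengths[order]
        bad_sorted = np.zeros_like(s_sorted, dtype=bool)
        bad_sorted[:, 1:] = s_sorted[:, 1:] < s_sorted[:, :-1] + l_sorted[:, :-1]
        if not bad_sorted.any():
            break
        bad = np.zeros_like(bad_sorted)
        np.put_along_axis(bad, order, bad_sorted, axis=1)
        redraw = rng.integers(0, chrom_len - lengths + 1, size=(n_perm, n))
        starts = np.where(bad, redraw, starts)
    return starts


def permutation_overlap_test(
    A: list[Interval],
    B: list[Interval],
    layout: GenomeLayout,
    max_dist: int = 0,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the overlap of A with B.

    Each permutation re-places every A interval uniformly at random on its own
    chromosome, preserving interval lengths and avoiding overlap among the
    re-placed intervals by rejection. The p-value is
    ``max(#{permuted >= observed}, 1) / n_perm`` (floor 1/n_perm) and the
    Z-score is (observed - mean) / sd of the permuted statistics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = intersect_with_tolerance(A, B, max_dist).n_intersect

    b_arr = _as_arrays(B)
    a_arr = _as_arrays(A)
    rng = np.random.default_rng(seed)
    perm_stats = np.zeros(n_perm, dtype=np.int64)
    for chrom in sorted(a_arr):
        starts_a, ends_a = a_arr[chrom]
        lengths = ends_a - starts_a
        chrom_len = layout.length_of(chrom)
        starts = _random_placement(lengths, chrom_len, n_perm, rng)
        if chrom not in b_arr:
            continue
        ts, te = b_arr[chrom]
        cummax_end = np.maximum.accumulate(te)
        ends = starts + lengths  # lengths broadcast over rows
        idx = np.searchsorted(ts, (ends + max_dist).ravel(), "right").reshape(ends.shape)
        hit = np.zeros(starts.shape, dtype=bool)
        nz = idx > 0
        hit[nz] = cummax_end[np.maximum(idx - 1, 0)][nz] >= (starts - max_dist)[nz]
        perm_stats += hit.sum(axis=1)

    mean = float(perm_stats.mean())
    sd = float(perm_stats.std(ddof=1)) if n_perm > 1 else 0.0
    if sd == 0:
        warnings.warn("permuted statistics are constant; Z-score reported as signed infinity")
        z = math_inf_signed(observed - mean)
    else:
        z = (observed - mean) / sd
    p = max(int((perm_stats >= observed).sum()), 1) / n_perm
    return PermutationResult(float(observed), mean, sd, float(z), float(p), n_perm)


def math_inf_signed(x: float) -> float:
    if x > 0:
        return float("inf")
    if x < 0:
        return float("-inf")
    return 0.0


def domain_relative_coverage(
    origins: list[OriginCall],
    domains: list[IniDomain],
    flank: int = 100_000,
    n_body_bins: int = 20,
    n_flank_bins: int = 10,
) -> dict[str, np.ndarray]:
    """Per-class origin-midpoint density over scaled domains with fixed-width flanks.

    Every domain body is mapped onto ``n_body_bins`` common bins; the two
    flanks are binned at fixed width ``flank / n_flank_bins``. Values are mean
    origin counts per domain per bin, keyed by class label (``None`` when
    origins are unclassed).
    """
    if not domains:
        raise ValueError("no domains supplied")
    labels = sorted({o.class_label for o in origins}, key=str)
    profiles = {lab: np.zeros(2 * n_flank_bins + n_body_bins) for lab in labels}
    flank_bin = flank / n_flank_bins
    for dom in domains:
        for o in origins:
            if o.chrom != dom.chrom:
                continue
            m = o.midpoint
            if dom.start <= m < dom.end:
                rel = (m - dom.start) / (dom.end - dom.start)
                b = n_flank_bins + min(int(rel * n_body_bins), n_body_bins - 1)
            elif dom.start - flank <= m < dom.start:
                b = int((m - (dom.start - flank)) / flank_bin)
            elif dom.end <= m < dom.end + flank:
                b = n_flank_bins + n_body_bins + min(
                    int((m - dom.end) / flank_bin), n_flank_bins - 1)
            else:
                continue
            profiles[o.class_label][b] += 1
    for lab in labels:
        profiles[lab] /= len(domains)
    return profiles
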