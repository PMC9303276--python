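"""The origin caller: window counting, enrichment filtering, island merging,
efficiency scoring, origin calling and efficiency classing.

The method contrasts a library of replicated (heavy-light, HL) reads against a
library of unreplicated (light-light, LL) reads. Origins are loci where HL
reads are enriched and LL reads are depleted. The pipeline is:

1. count reads in fixed windows (default 100 bp) for both libraries,
2. normalize each library's counts to reads-per-million of its own total,
3. keep windows with log2(HL/LL) >= 2 on normalized counts,
4. merge kept windows separated by <= 500 bp and retain islands >= 200 bp,
5. recount reads over each island, renormalize, score E = HL/(HL+LL), and
   call the island an origin when E >= 0.8,
6. assign Z-scores over the called set and split into equal-size classes
   (high / medium / low for the default three).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Interval, ReadSet

logger = logging.getLogger(__name__)

CLASS_LABELS_3 = ("high", "medium", "low")


@dataclass(frozen=True)
class CallerParams:
    """Tunable parameters of the origin caller (defaults are the method's)."""

    window_size: int = 100
    min_log2_ratio: float = 2.0
    merge_gap: int = 500
    min_island_length: int = 200
    min_efficiency: float = 0.8
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.min_island_length <= 0:
            raise ValueError("min_island_length must be positive")
        if not 0 < self.min_efficiency <= 1:
            raise ValueError("min_efficiency must be in (0, 1]")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


@dataclass
class WindowCounts:
    """Per-window read counts for one library over a genome layout.

    The last window of each chromosome may be shorter than ``window_size``;
    it is kept and treated like any other window.
    """

    layout: GenomeLayout
    window_size: int
    raw: dict[str, np.ndarray]
    library_total: int

    def n_windows(self, chrom: str) -> int:
        return -(-self.layout.length_of(chrom) // self.window_size)

    def normalized(self, chrom: str) -> np.ndarray:
        """Reads-per-million: raw * 1e6 / library_total."""
        if self.library_total <= 0:
            raise ValueError("library_total must be positive to normalize")
        return self.raw[chrom] * (1e6 / self.library_total)


def count_reads_in_windows(
    reads: ReadSet, layout: GenomeLayout, window_size: int
) -> WindowCounts:
    """Count reads into fixed windows by their 5'-most coordinate.

    Each read contributes exactly 1 to the single window containing its start,
    so raw counts sum to the library size.
    """
    raw: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        n_win = -(-layout.length_of(chrom) // window_size)
        starts = reads.starts.get(chrom)
        if starts is None or starts.size == 0:
            raw[chrom] = np.zeros(n_win, dtype=np.int64)
        else:
            raw[chrom] = np.bincount(starts // window_size, minlength=n_win).astype(np.int64)
    return WindowCounts(layout, window_size, raw, library_total=reads.total)


def normalize_counts(counts: WindowCounts, library_total: int) -> WindowCounts:
    """Attach the library total used for reads-per-million normalization."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return replace(counts, library_total=library_total)


def filter_enriched_windows(
    hl: WindowCounts, ll: WindowCounts, min_log2_ratio: float = 2.0
) -> dict[str, np.ndarray]:
    """Boolean mask of windows with log2(HL/LL) >= threshold on normalized counts.

    Windows with complete LL depletion (LL = 0) pass whenever they carry any HL
    signal: these are the highest-confidence origins and a pseudocount would cap
    their score. Windows without HL signal never pass.
    """
    if hl.layout != ll.layout or hl.window_size != ll.window_size:
        raise ValueError("HL and LL window counts must share layout and window size")
    masks: dict[str, np.ndarray] = {}
    for chrom in hl.layout.names:
        h = hl.normalized(chrom)
        l = ll.normalized(chrom)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_ok = np.log2(np.where(l > 0, h / np.where(l > 0, l, 1.0), np.inf)) >= min_log2_ratio
        masks[chrom] = (h > 0) & ((l == 0) | ratio_ok)
    return masks


def windows_to_intervals(
    mask: dict[str, np.ndarray], layout: GenomeLayout, window_size: int
) -> list[Interval]:
    """Convert a per-window boolean mask into sorted window intervals."""
    out: list[Interval] = []
    for chrom in layout.names:
        m = mask.get(chrom)
        if m is None:
            continue
        L = layout.length_of(chrom)
        for idx in np.flatnonzero(m):
            start = int(idx) * window_size
            out.append(Interval(chrom, start, min(start + window_size, L)))
    return out


def merge_windows_to_islands(
    windows: list[Interval], merge_gap: int = 500, min_island_length: int = 200
) -> list[Interval]:
    """Merge windows <= ``merge_gap`` apart (transitively) and keep runs >= ``min_island_length``.

    Two windows merge iff the start of the later minus the end of the earlier
    is <= merge_gap; chromosomes are handled independently.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    islands: list[Interval] = []
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start, w.end))
        cur_start, cur_end = ws[0].start, ws[0].end
        for w in ws[1:]:
            if w.start - cur_end <= merge_gap:
                cur_end = max(cur_end, w.end)
            else:
                if cur_end - cur_start >= min_island_length:
                    islands.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = w.start, w.end
        if cur_end - cur_start >= min_island_length:
            islands.append(Interval(chrom, cur_start, cur_end))
    return sorted(islands, key=Interval.sort_key)


@dataclass
class Island:
    """A candidate origin: a merged run of enriched windows with recounted signal."""

    chrom: str
    start: int
    end: int
    hl_norm: float
    ll_norm: float

    @property
    def efficiency(self) -> float:
        return self.hl_norm / (self.hl_norm + self.ll_norm)

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


def _count_in_interval(reads: ReadSet, chrom: str, start: int, end: int) -> int:
    starts = reads.starts.get(chrom)
    if starts is None:
        return 0
    return int(np.searchsorted(starts, end, "left") - np.searchsorted(starts, start, "left"))


def score_islands(
    islands: list[Interval],
    hl: ReadSet,
    ll: ReadSet,
    hl_total: int | None = None,
    ll_total: int | None = None,
) -> list[Island]:
    """Recount both libraries over each island, renormalize and score E = HL/(HL+LL).

    Recounting uses the same 5'-start assignment and the same library totals as
    windowing. Islands with no HL signal are discarded (with a warning when
    they carry no signal at all).
    """
    hl_total = hl.total if hl_total is None else hl_total
    ll_total = ll.total if ll_total is None else ll_total
    if hl_total <= 0 or ll_total <= 0:
        raise ValueError("library totals must be positive")
    out: list[Island] = []
    for iv in islands:
        h = _count_in_interval(hl, iv.chrom, iv.start, iv.end)
        l = _count_in_interval(ll, iv.chrom, iv.start, iv.end)
        if h == 0:
            if l == 0:
                logger.warning(
                    "island %s:%d-%d has zero reads in both libraries; discarded",
                    iv.chrom, iv.start, iv.end,
                )
            continue
        out.append(
            Island(iv.chrom, iv.start, iv.end, h * 1e6 / hl_total, l * 1e6 / ll_total)
        )
    return out


@dataclass
class OriginCall:
    """A called origin with its normalized counts, efficiency and class."""

    chrom: str
    start: int
    end: int
    hl_norm: float
    ll_norm: float
    efficiency: float
    z_score: float = math.nan
    class_label: str | None = None
    name: str | None = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, name=self.name,
                        score=self.efficiency)


def call_origins(
    hl: ReadSet,
    ll: ReadSet,
    layout: GenomeLayout,
    params: CallerParams = CallerParams(),
) -> list[OriginCall]:
    """Run the full caller; returns unclassed origins sorted by position."""
    if hl.total == 0 or ll.total == 0:
        raise ValueError("both libraries must be non-empty")
    hl_counts = count_reads_in_windows(hl, layout, params.window_size)
    ll_counts = count_reads_in_windows(ll, layout, params.window_size)
    mask = filter_enriched_windows(hl_counts, ll_counts, params.min_log2_ratio)
    windows = windows_to_intervals(mask, layout, params.window_size)
    islands = merge_windows_to_islands(windows, params.merge_gap, params.min_island_length)
    scored = score_islands(islands, hl, ll)
    calls = [
        OriginCall(i.chrom, i.start, i.end, i.hl_norm, i.ll_norm, i.efficiency)
        for i in scored
        if i.efficiency >= params.min_efficiency
    ]
    calls.sort(key=lambda o: (o.chrom, o.start, o.end))
    for k, call in enumerate(calls, start=1):
        call.name = f"origin_{k}"
    return calls


def class_origins_by_efficiency(
    origins: list[OriginCall], n_classes: int = 3
) -> list[OriginCall]:
    """Assign efficiency Z-scores and split origins into equal-size classes.

    Z = (E - mean(E)) / sd(E) with the sample standard deviation. Origins are
    ranked by Z descending (ties broken by genomic coordinate) and cut into
    ``n_classes`` contiguous groups whose sizes differ by at most one; for the
    default three classes the labels are high / medium / low from the top.
    Returns the same objects, annotated, in genomic order.
    """
    n = len(origins)
    if n < n_classes:
        raise ValueError(f"need at least {n_classes} origins to form {n_classes} classes")
    eff = np.array([o.efficiency for o in origins])
    sd = eff.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        logger.warning("zero efficiency spread; Z-scores all 0, classing by position")
        z = np.zeros(n)
    else:
        z = (eff - eff.mean()) / sd
    for o, zi in zip(origins, z):
        o.z_score = float(zi)
    order = sorted(range(n), key=lambda i: (-z[i], origins[i].chrom, origins[i].start))
    if n_classes == 3:
        labels = CLASS_LABELS_3
    else:
        labels = tuple(f"class{i + 1}" for i in range(n_classes))
    base, extra = divmod(n, n_classes)
    pos = 0
    for ci in range(n_classes):
        size = base + (1 if ci < extra else 0)
        for i in order[pos:pos + size]:
            origins[i].class_label = labels[ci]
        pos += size
    return origins


def saturation_curve(
    hl: ReadSet,
    ll: ReadSet,
    layout: GenomeLayout,
    params: CallerParams,
    fractions: list[float],
    mode: str = "joint",
    seed: int = 0,
) -> pd.DataFrame:
    """Origin count as a function of sequencing depth, by seeded subsampling.

    ``mode="joint"`` subsamples both libraries at each fraction; ``"fixed_ll"``
    keeps the full LL library and varies only HL.
    """
    if mode not in ("joint", "fixed_ll"):
        raise ValueError("mode must be 'joint' or 'fixed_ll'")
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    rows = []
    for f in fractions:
        rng = np.random.default_rng([seed, int(round(f * 10**6))])
        hl_sub = hl.subsample(f, rng)
        ll_sub = ll.subsample(f, rng) if mode == "joint" else ll
        try:
            n_origins = len(call_origins(hl_sub, ll_sub, layout, params))
        except ValueError:  # subsample emptied a library
            n_origins = 0
        rows.append(
            {"fraction": f, "hl_reads_used": hl_sub.total,
             "ll_reads_used": ll_sub.total, "n_origins": n_origins}
        )
    return pd.DataFrame(rows)


def origins_to_dataframe(origins: list[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [o.chrom for o in origins],
            "start": [o.start for o in origins],
            "end": [o.end for o in origins],
            "name": [o.name for o in origins],
            "efficiency": [o.efficiency for o in origins],
            "z_score": [o.z_score for o in origins],
            "class": [o.class_label for o in origins],
            "hl_norm": [o.hl_norm for o in origins],
            "ll_norm": [o.ll_norm for o in origins],
        }
    )
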