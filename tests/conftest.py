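"""Shared fixtures and the independent brute-force caller oracle.

The oracle re-implements the five caller steps (window counting, per-million
normalization, log2-ratio filtering, gap merging, island recounting/scoring)
with plain Python loops and no shared code, so pipeline results can be
checked for exact agreement.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from iniseq2 import CallerParams, GenomeLayout, Interval, ReadSet


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout((("chr1", 1_000_000), ("chr2", 500_000)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_reads(layout: GenomeLayout, starts_by_chrom: dict[str, list[int]],
               read_length: int = 50) -> ReadSet:
    return ReadSet(
        {c: np.asarray(v, dtype=np.int64) for c, v in starts_by_chrom.items()},
        read_length,
        layout,
    )


@pytest.fixture
def reads_factory():
    return make_reads


# --- independent brute-force oracle -------------------------------------------------


def brute_force_call(
    hl_starts: dict[str, list[int]],
    ll_starts: dict[str, list[int]],
    chrom_lengths: dict[str, int],
    params: CallerParams,
) -> list[tuple[str, int, int, float]]:
    """Plain-Python re-implementation of the caller; returns (chrom, start, end, E)."""
    w = params.window_size
    hl_total = sum(len(v) for v in hl_starts.values())
    ll_total = sum(len(v) for v in ll_starts.values())

    def window_counts(starts_by_chrom):
        counts = {}
        for chrom, L in chrom_lengths.items():
            n_win = (L + w - 1) // w
            c = [0] * n_win
            for s in starts_by_chrom.get(chrom, []):
                c[s // w] += 1
            counts[chrom] = c
        return counts

    hl_counts = window_counts(hl_starts)
    ll_counts = window_counts(ll_starts)

    origins = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        passing = []  # (win_start, win_end)
        for i, (h, l) in enumerate(zip(hl_counts[chrom], ll_counts[chrom])):
            hn = h * 1e6 / hl_total
            ln = l * 1e6 / ll_total
            if hn <= 0:
                continue
            if ln == 0 or math.log2(hn / ln) >= params.min_log2_ratio:
                passing.append((i * w, min(i * w + w, L)))
        # merge windows <= merge_gap apart, keep >= min_island_length
        islands = []
        run_start = run_end = None
        for s, e in passing:
            if run_start is None:
                run_start, run_end = s, e
            elif s - run_end <= params.merge_gap:
                run_end = e
            else:
                if run_end - run_start >= params.min_island_length:
                    islands.append((run_start, run_end))
                run_start, run_end = s, e
        if run_start is not None and run_end - run_start >= params.min_island_length:
            islands.append((run_start, run_end))
        # recount, score, call
        for s, e in islands:
            h = sum(1 for x in hl_starts.get(chrom, []) if s <= x < e)
            l = sum(1 for x in ll_starts.get(chrom, []) if s <= x < e)
            if h == 0:
                continue
            hn = h * 1e6 / hl_total
            ln = l * 1e6 / ll_total
            eff = hn / (hn + ln)
            if eff >= params.min_efficiency:
                origins.append((chrom, s, e, eff))
    return origins


@pytest.fixture
def brute_force_caller():
    return brute_force_call


def random_count_genome(seed: int):
    """A small random genome plus HL/LL read libraries with planted hot spots."""
    g = np.random.default_rng(seed)
    n_chrom = int(g.integers(1, 3))
    lengths = {f"c{k}": int(g.integers(5_000, 100_000 // n_chrom)) for k in range(n_chrom)}
    layout = GenomeLayout(tuple(lengths.items()))
    hl, ll = {}, {}
    for chrom, L in lengths.items():
        n_bg = int(g.integers(50, 400))
        hl_list = list(g.integers(0, L - 50, size=n_bg))
        ll_list = list(g.integers(0, L - 50, size=2 * n_bg))
        for _ in range(int(g.integers(0, 4))):  # planted enriched spots
            centre = int(g.integers(500, max(501, L - 500)))
            width = int(g.integers(100, 800))
            n_hot = int(g.integers(5, 120))
            lo = max(0, centre - width)
            hi = min(L - 50, centre + width)
            hl_list += list(g.integers(lo, hi, size=n_hot))
            ll_list += list(g.integers(lo, hi, size=max(1, n_hot // 20)))
        hl[chrom] = sorted(int(x) for x in hl_list)
        ll[chrom] = sorted(int(x) for x in ll_list)
    return layout, hl, ll


@pytest.fixture
def random_genome_factory():
    return random_count_genome
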