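"""Unit and property tests for the origin caller."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iniseq2 import (
    CallerParams,
    GenomeLayout,
    Interval,
    call_origins,
    class_origins_by_efficiency,
    count_reads_in_windows,
    filter_enriched_windows,
    merge_windows_to_islands,
    normalize_counts,
    saturation_curve,
    score_islands,
    windows_to_intervals,
)
from iniseq2.caller import OriginCall


class TestWindowCounting:
    def test_reads_assigned_by_five_prime_start(self, reads_factory):
        layout = GenomeLayout((("chr1", 300),))
        reads = reads_factory(layout, {"chr1": [10, 150, 160]}, read_length=50)
        wc = count_reads_in_windows(reads, layout, 100)
        assert wc.raw["chr1"].tolist() == [1, 2, 0]

    def test_no_reads_gives_zero_vector(self, reads_factory):
        layout = GenomeLayout((("chr1", 300), ("chr2", 250)))
        reads = reads_factory(layout, {"chr1": [0]})
        wc = count_reads_in_windows(reads, layout, 100)
        assert wc.raw["chr2"].tolist() == [0, 0, 0]

    def test_boundary_spanning_read_counted_once(self, reads_factory):
        # a 50 bp read starting at 95 spans the window boundary but counts
        # only in the window holding its start
        layout = GenomeLayout((("chr1", 300),))
        reads = reads_factory(layout, {"chr1": [95]})
        wc = count_reads_in_windows(reads, layout, 100)
        assert wc.raw["chr1"].tolist() == [1, 0, 0]
        assert wc.raw["chr1"].sum() == reads.total

    def test_short_last_window_retained(self, reads_factory):
        layout = GenomeLayout((("chr1", 250),))
        reads = reads_factory(layout, {"chr1": [190]}, read_length=50)
        wc = count_reads_in_windows(reads, layout, 100)
        assert len(wc.raw["chr1"]) == 3  # [0,100) [100,200) [200,250)


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,total,expected", [(5, 10**6, 5.0), (0, 10**6, 0.0), (200, 2 * 10**8, 1.0)]
    )
    def test_reads_per_million(self, reads_factory, raw, total, expected):
        layout = GenomeLayout((("chr1", 100),))
        reads = reads_factory(layout, {"chr1": [0] * raw}) if raw else None
        if raw:
            wc = count_reads_in_windows(reads, layout, 100)
        else:
            from iniseq2.caller import WindowCounts

            wc = WindowCounts(layout, 100, {"chr1": np.zeros(1, dtype=np.int64)}, 1)
        wc = normalize_counts(wc, total)
        assert wc.normalized("chr1")[0] == pytest.approx(expected)

    def test_nonpositive_total_rejected(self, reads_factory):
        layout = GenomeLayout((("chr1", 100),))
        wc = count_reads_in_windows(reads_factory(layout, {"chr1": [0]}), layout, 100)
        with pytest.raises(ValueError):
            normalize_counts(wc, 0)


def _counts(layout, window, hl_norm, ll_norm):
    """WindowCounts pair with the given normalized values (total 1e6)."""
    from iniseq2.caller import WindowCounts

    hl = WindowCounts(layout, window, {"chr1": np.asarray(hl_norm, dtype=np.int64)}, 10**6)
    ll = WindowCounts(layout, window, {"chr1": np.asarray(ll_norm, dtype=np.int64)}, 10**6)
    return hl, ll


class TestEnrichmentFilter:
    @pytest.mark.parametrize(
        "h,l,expected",
        [
            (4, 1, True),  # log2 = 2, boundary passes
            (39, 10, False),  # 3.9x fails
            (1, 0, True),  # complete LL depletion passes
            (0, 0, False),  # no HL signal never passes
            (0, 5, False),
        ],
    )
    def test_filter_rule(self, h, l, expected):
        layout = GenomeLayout((("chr1", 100),))
        hl, ll = _counts(layout, 100, [h], [l])
        mask = filter_enriched_windows(hl, ll, 2.0)
        assert mask["chr1"][0] == expected

    def test_mismatched_layout_rejected(self):
        l1 = GenomeLayout((("chr1", 100),))
        l2 = GenomeLayout((("chr1", 200),))
        hl, _ = _counts(l1, 100, [1], [1])
        _, ll = _counts(l2, 100, [1, 0], [1, 0])
        with pytest.raises(ValueError):
            filter_enriched_windows(hl, ll)


class TestIslandMerging:
    def test_gap_within_tolerance_merges(self):
        ws = [Interval("chr1", 0, 100), Interval("chr1", 400, 500)]
        assert merge_windows_to_islands(ws, 500, 200) == [Interval("chr1", 0, 500)]

    def test_isolated_short_island_dropped(self):
        assert merge_windows_to_islands([Interval("chr1", 0, 100)], 500, 200) == []

    def test_gap_beyond_tolerance_splits(self):
        ws = [Interval("chr1", 0, 100), Interval("chr1", 700, 800)]
        assert merge_windows_to_islands(ws, 500, 200) == []  # two 100 bp islands dropped

    def test_chromosomes_independent(self):
        ws = [Interval("chr1", 0, 100), Interval("chr2", 150, 250)]
        assert merge_windows_to_islands(ws, 500, 100) == sorted(ws, key=Interval.sort_key)

    @pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools unavailable")
    def test_matches_bedtools_merge(self, tmp_path, rng):
        # independent oracle for the merge step (tolerance semantics of merge -d)
        starts = np.unique(rng.integers(0, 500, size=60)) * 100
        ws = [Interval("chr1", int(s), int(s) + 100) for s in starts]
        bed = tmp_path / "w.bed"
        bed.write_text("".join(f"chr1\t{w.start}\t{w.end}\n" for w in ws))
        out = subprocess.run(
            ["bedtools", "merge", "-d", "500", "-i", str(bed)],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = []
        for line in out.strip().splitlines():
            c, s, e = line.split("\t")
            if int(e) - int(s) >= 200:
                expected.append(Interval(c, int(s), int(e)))
        assert merge_windows_to_islands(ws, 500, 200) == expected


class TestIslandScoring:
    def test_efficiency_at_four_to_one(self, reads_factory):
        # normalized HL exactly 4x LL sits exactly at the calling threshold
        layout = GenomeLayout((("chr1", 1000),))
        hl = reads_factory(layout, {"chr1": [10, 20, 30, 40]})
        ll = reads_factory(layout, {"chr1": [15]})
        islands = score_islands(
            [Interval("chr1", 0, 500)], hl, ll, hl_total=10**6, ll_total=10**6
        )
        assert islands[0].efficiency == pytest.approx(0.8)

    def test_complete_ll_depletion_scores_one(self, reads_factory):
        layout = GenomeLayout((("chr1", 1000),))
        hl = reads_factory(layout, {"chr1": list(range(0, 700, 100))})
        ll = reads_factory(layout, {"chr1": [900]})
        islands = score_islands([Interval("chr1", 0, 800)], hl, ll)
        assert islands[0].efficiency == 1.0

    def test_balanced_counts_score_half(self, reads_factory):
        layout = GenomeLayout((("chr1", 1000),))
        hl = reads_factory(layout, {"chr1": [10]})
        ll = reads_factory(layout, {"chr1": [20]})
        islands = score_islands([Interval("chr1", 0, 500)], hl, ll)
        assert islands[0].efficiency == pytest.approx(0.5)

    def test_zero_signal_island_discarded_with_warning(self, reads_factory, caplog):
        layout = GenomeLayout((("chr1", 1000),))
        hl = reads_factory(layout, {"chr1": [900]})
        ll = reads_factory(layout, {"chr1": [900]})
        with caplog.at_level("WARNING"):
            islands = score_islands([Interval("chr1", 0, 500)], hl, ll)
        assert islands == []
        assert "zero reads" in caplog.text


class TestThresholdIdentity:
    @settings(max_examples=300, derandomize=True)
    @given(h=st.integers(1, 10**6), l=st.integers(1, 10**6))
    def test_efficiency_and_log2_ratio_thresholds_agree(self, h, l):
        # E >= 0.8  <=>  HL/LL >= 4  <=>  log2(HL/LL) >= 2 for positive counts
        eff = h / (h + l)
        assert (eff >= 0.8) == (np.log2(h / l) >= 2.0)


class TestCallOrigins:
    def test_uniform_background_yields_no_origins(self, reads_factory, rng):
        layout = GenomeLayout((("chr1", 100_000),))
        hl = reads_factory(layout, {"chr1": np.sort(rng.integers(0, 99_950, 30_000))})
        ll = reads_factory(layout, {"chr1": np.sort(rng.integers(0, 99_950, 30_000))})
        assert call_origins(hl, ll, layout) == []

    def test_single_planted_origin_recovered(self):
        from iniseq2 import (
            PlantedOrigin,
            SimulationConfig,
            emit_read_libraries,
            simulate_replicated_fraction,
        )

        layout = GenomeLayout((("chrT", 50_000),))
        cfg = SimulationConfig(
            layout=layout,
            origins=[PlantedOrigin("chrT", 25_000, 0.95, 3_400.0)],
            seed=11,
        )
        truth = simulate_replicated_fraction(cfg)
        hl, ll = emit_read_libraries(truth)
        origins = call_origins(hl, ll, cfg.layout)
        assert len(origins) == 1
        assert origins[0].start <= 25_000 < origins[0].end

    def test_matches_brute_force_oracle(self, brute_force_caller, random_genome_factory,
                                        reads_factory):
        params = CallerParams()
        for seed in range(5):
            layout, hl_starts, ll_starts = random_genome_factory(seed)
            hl = reads_factory(layout, hl_starts)
            ll = reads_factory(layout, ll_starts)
            got = [
                (o.chrom, o.start, o.end, o.efficiency)
                for o in call_origins(hl, ll, layout, params)
            ]
            expected = brute_force_caller(hl_starts, ll_starts, layout.lengths, params)
            assert got == expected

    def test_normalization_invariance_under_depth_doubling(self, reads_factory,
                                                           random_genome_factory):
        # duplicating every read in both libraries must not change calls or E
        layout, hl_starts, ll_starts = random_genome_factory(42)
        hl = reads_factory(layout, hl_starts)
        ll = reads_factory(layout, ll_starts)
        hl2 = reads_factory(layout, {c: sorted(v + v) for c, v in hl_starts.items()})
        ll2 = reads_factory(layout, {c: sorted(v + v) for c, v in ll_starts.items()})
        a = [(o.chrom, o.start, o.end, o.efficiency) for o in call_origins(hl, ll, layout)]
        b = [(o.chrom, o.start, o.end, o.efficiency) for o in call_origins(hl2, ll2, layout)]
        assert a == b

    def test_called_origins_disjoint_and_sorted(self, reads_factory, random_genome_factory):
        layout, hl_starts, ll_starts = random_genome_factory(7)
        origins = call_origins(
            reads_factory(layout, hl_starts), reads_factory(layout, ll_starts), layout
        )
        for a, b in zip(origins, origins[1:]):
            if a.chrom == b.chrom:
                assert b.start - a.end > 500  # separated by more than the merge gap


def _origins_with_eff(effs):
    out = []
    for k, e in enumerate(effs):
        h = e * 100
        out.append(OriginCall("chr1", 1000 * k, 1000 * k + 500, h, 100 - h, e))
    return out


class TestClassing:
    def test_six_origins_two_per_class(self):
        origins = _origins_with_eff([0.81, 0.85, 0.9, 0.95, 0.99, 1.0])
        classed = class_origins_by_efficiency(origins)
        by_label = {}
        for o in classed:
            by_label.setdefault(o.class_label, []).append(o.efficiency)
        assert {k: len(v) for k, v in by_label.items()} == {"high": 2, "medium": 2, "low": 2}
        assert sorted(by_label["high"]) == [0.99, 1.0]

    def test_three_origins_one_per_class(self):
        classed = class_origins_by_efficiency(_origins_with_eff([0.8, 0.9, 1.0]))
        assert {o.class_label for o in classed} == {"high", "medium", "low"}

    def test_mean_efficiency_gets_zero_z(self):
        classed = class_origins_by_efficiency(_origins_with_eff([0.8, 0.9, 1.0]))
        assert classed[1].z_score == pytest.approx(0.0)

    def test_zero_spread_falls_back_to_position(self, caplog):
        with caplog.at_level("WARNING"):
            classed = class_origins_by_efficiency(_origins_with_eff([0.9, 0.9, 0.9]))
        assert [o.class_label for o in classed] == ["high", "medium", "low"]
        assert all(o.z_score == 0 for o in classed)

    def test_too_few_origins_rejected(self):
        with pytest.raises(ValueError):
            class_origins_by_efficiency(_origins_with_eff([0.9, 1.0]))


@pytest.fixture(scope="module")
def sim_libraries():
    # strong, well-separated origins: the discoverable set is unambiguous,
    # so the subsampling curve saturates at the full call
    from iniseq2 import (
        PlantedOrigin,
        SimulationConfig,
        emit_read_libraries,
        simulate_replicated_fraction,
    )

    layout = GenomeLayout((("chrS", 105_000),))
    g = np.random.default_rng(3)
    origins = [
        PlantedOrigin("chrS", 10_000 * (k + 1), float(g.uniform(0.88, 1.0)), 3_400.0)
        for k in range(10)
    ]
    cfg = SimulationConfig(layout=layout, origins=origins, seed=5)
    truth = simulate_replicated_fraction(cfg)
    hl, ll = emit_read_libraries(truth)
    return cfg.layout, hl, ll


class TestSaturation:

    def test_full_fraction_equals_full_call(self, sim_libraries):
        layout, hl, ll = sim_libraries
        params = CallerParams()
        table = saturation_curve(hl, ll, layout, params, [1.0], seed=3)
        assert table.n_origins.iloc[0] == len(call_origins(hl, ll, layout, params))

    def test_counts_nondecreasing_with_depth(self, sim_libraries):
        layout, hl, ll = sim_libraries
        counts = []
        for frac in (0.1, 0.5, 1.0):
            reps = [
                saturation_curve(hl, ll, layout, CallerParams(), [frac], "joint", seed).n_origins.iloc[0]
                for seed in range(10)
            ]
            counts.append(np.mean(reps))
        assert counts[0] <= counts[1] <= counts[2]

    def test_invalid_fraction_rejected(self, sim_libraries):
        layout, hl, ll = sim_libraries
        with pytest.raises(ValueError):
            saturation_curve(hl, ll, layout, CallerParams(), [0.0])

    def test_fixed_ll_mode_keeps_ll_library(self, sim_libraries):
        layout, hl, ll = sim_libraries
        table = saturation_curve(hl, ll, layout, CallerParams(), [0.5], "fixed_ll", seed=1)
        assert table.ll_reads_used.iloc[0] == ll.total
        assert table.hl_reads_used.iloc[0] < hl.total
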