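"""Transcribed-region segmentation, shuffles, overlap enrichment and event ops."""
import numpy as np
import pytest
from scipy import stats

import oracles
from pipseq.coverage import CoverageTrack
from pipseq.enrichment import (
    BackgroundSegments,
    ContingencyTable,
    events_per_interval,
    merge_nearby_events,
    overlap_enrichment,
    segment_transcribed_regions,
    shuffle_intervals,
)
from pipseq.model import GenomicInterval, Strand


def _track(values):
    arr = np.asarray(values)
    return CoverageTrack(
        {("chr1", Strand.PLUS): arr, ("chr1", Strand.MINUS): np.zeros_like(arr)}, 100
    )


class TestTranscribedSegmentation:
    def test_qualifying_run_kept(self):
        segs = segment_transcribed_regions(_track([0] * 5 + [12] * 20 + [0] * 5))
        assert [(s.start, s.end) for s in segs.segments] == [(5, 25)]

    def test_short_run_dropped(self):
        segs = segment_transcribed_regions(_track([0] * 5 + [12] * 10 + [0] * 5))
        assert segs.segments == []

    def test_sub_threshold_gap_merged(self):
        vals = [12] * 10 + [3] * 8 + [12] * 10
        segs = segment_transcribed_regions(_track(vals))
        assert [(s.start, s.end) for s in segs.segments] == [(0, 28)]

    def test_matches_brute_force_on_random_coverage(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            vals = rng.integers(0, 25, size=120)
            got = [
                (s.start, s.end)
                for s in segment_transcribed_regions(_track(vals)).segments
            ]
            assert got == oracles.brute_segments(vals, 10, 10, 15)


def _background(*pairs):
    return BackgroundSegments(
        [GenomicInterval("chr1", s, e, Strand.PLUS) for s, e in pairs],
        threshold=10,
        max_gap=10,
        min_run=15,
    )


class TestShuffles:
    def test_forced_placement_in_single_segment(self):
        bg = _background((100, 150))
        (placed,) = shuffle_intervals([50], bg, n_sets=1, seed=0)
        assert (placed[0].start, placed[0].end) == (100, 150)

    def test_size_multiset_preserved_and_inside_background(self):
        bg = _background((0, 300), (1000, 1200), (5000, 5400))
        sizes = [20, 20, 35, 50, 120]
        sets = shuffle_intervals(sizes, bg, n_sets=10, seed=4)
        assert len(sets) == 10
        for placed in sets:
            assert sorted(iv.length for iv in placed) == sorted(sizes)
            for iv in placed:
                assert any(
                    seg.start <= iv.start and iv.end <= seg.end for seg in bg.segments
                )

    def test_seeded_determinism(self):
        bg = _background((0, 500))
        a = shuffle_intervals([30, 40], bg, n_sets=3, seed=9)
        b = shuffle_intervals([30, 40], bg, n_sets=3, seed=9)
        assert a == b

    def test_start_positions_uniform_over_valid_range(self):
        bg = _background((0, 59))  # 50 valid starts for a 10-mer
        starts = [
            placed[0].start
            for placed in shuffle_intervals([10], bg, n_sets=10000, seed=2)
        ]
        counts = np.bincount(starts, minlength=50)
        chi2 = ((counts - 200.0) ** 2 / 200.0).sum()
        assert stats.chi2.sf(chi2, df=49) > 0.01


class TestOverlapEnrichment:
    def test_log2_arithmetic(self):
        # observed 2 of 2 overlapping; shuffles average 0.5 of 2
        query = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 50, 60)]
        subject = [GenomicInterval("chr1", 0, 100)]
        hits = [query, [GenomicInterval("chr1", 500, 510), GenomicInterval("chr1", 600, 610)]]
        res = overlap_enrichment(query, subject, hits)
        assert res.observed == 2
        assert res.expected == pytest.approx(1.0)
        assert res.log2_enrichment == pytest.approx(1.0)

    def test_chi_squared_closed_form(self):
        table = ContingencyTable([[30, 70], [10, 90]])
        stat, p = table.chi_squared()
        assert stat == pytest.approx(12.5)
        assert stat == pytest.approx(oracles.chi2_closed_form(30, 70, 10, 90))

    def test_chi_squared_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(41)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 200, size=4))
            if a + b == 0 or c + d == 0:
                continue
            stat, _ = ContingencyTable([[a, b], [c, d]]).chi_squared()
            assert stat == pytest.approx(
                oracles.chi2_closed_form(a, b, c, d), rel=1e-9, abs=1e-12
            )

    def test_degenerate_column_handled(self):
        stat, p = ContingencyTable([[5, 0], [7, 0]]).chi_squared()
        assert stat == 0.0 and p == 1.0

    def test_self_comparison_is_null(self):
        bg = _background((0, 20000), (30000, 45000))
        sizes = [30] * 400
        sets = shuffle_intervals(sizes, bg, n_sets=11, seed=13)
        subject = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(450)]
        res = overlap_enrichment(sets[0], subject, sets[1:])
        assert res.log2_enrichment == pytest.approx(0.0, abs=0.15)
        assert res.p_value > 0.01


class TestEventMerging:
    def test_merge_and_split_cases(self):
        ev = [GenomicInterval("chr1", 100, 101), GenomicInterval("chr1", 130, 131)]
        merged = merge_nearby_events(ev, max_dist=40)
        assert [(m.start, m.end) for m in merged] == [(100, 131)]
        ev2 = [GenomicInterval("chr1", 100, 101), GenomicInterval("chr1", 150, 151)]
        assert len(merge_nearby_events(ev2, max_dist=40)) == 2
        # boundary: exactly 40 apart stays separate ("less than 40" merges)
        ev3 = [GenomicInterval("chr1", 100, 101), GenomicInterval("chr1", 140, 141)]
        assert len(merge_nearby_events(ev3, max_dist=40)) == 2

    def test_idempotence(self):
        rng = np.random.default_rng(47)
        events = [
            GenomicInterval("chr1", int(p), int(p) + 1)
            for p in np.unique(rng.integers(0, 3000, size=200))
        ]
        once = merge_nearby_events(events, max_dist=40)
        twice = merge_nearby_events(once, max_dist=40)
        assert once == twice


class TestEventsPerInterval:
    def test_contained_event_counts(self):
        pps = [GenomicInterval("chr1", 0, 50)]
        events = [GenomicInterval("chr1", p, p + 1) for p in (5, 10, 20, 80)]
        res = events_per_interval(pps, events)
        assert res.counts.tolist() == [3]
        assert res.histogram == {3: 1}

    def test_no_events_all_zero(self):
        pps = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 100, 150)]
        res = events_per_interval(pps, [])
        assert res.counts.tolist() == [0, 0]

    def test_planted_density_ratio_vs_shuffles(self):
        # events at 5x per-base density inside sparse PPSs (2% of the
        # background): per-PPS mean should be ~5x the shuffled baseline
        rng = np.random.default_rng(53)
        spacing = 2500
        pps = [
            GenomicInterval("chr1", i * spacing, i * spacing + 50, Strand.PLUS)
            for i in range(50)
        ]
        genome = 50 * spacing
        bg = _background((0, genome))
        inside = np.zeros(genome, dtype=bool)
        for p in pps:
            inside[p.start : p.end] = True
        rates = np.where(inside, 0.10, 0.02)
        hits = np.flatnonzero(rng.random(genome) < rates)
        events = [GenomicInterval("chr1", int(b), int(b) + 1) for b in hits]
        shuffles = shuffle_intervals([50] * 50, bg, n_sets=10, seed=3)
        res = events_per_interval(pps, events, shuffles)
        assert res.shuffled_mean is not None
        assert res.mean / res.shuffled_mean == pytest.approx(5.0, rel=0.2)
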