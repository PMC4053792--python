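"""The Poisson enrichment score, segmentation, permutation FDR and calling."""
import numpy as np
import pytest

import oracles
from pipseq.caller import (
    SCORE_CAP,
    CallerConfig,
    ScoreProfile,
    call_pps,
    enrichment_score_profile,
    permutation_fdr,
    poisson_enrichment_score,
    saturation_curve,
    segment_regions,
)
from pipseq.coverage import AlignedSegment, CoverageTrack, Library
from pipseq.model import Strand
from pipseq.simulate import evaluate_recovery


def _tracks(f_arr, c_arr, n_fp=100, n_ctl=100):
    key = ("chr1", Strand.PLUS)
    key2 = ("chr1", Strand.MINUS)
    zeros = np.zeros_like(np.asarray(f_arr))
    fp = CoverageTrack({key: np.asarray(f_arr), key2: zeros.copy()}, n_fp)
    ctl = CoverageTrack({key: np.asarray(c_arr), key2: zeros.copy()}, n_ctl)
    return fp, ctl


class TestPoissonScore:
    def test_zero_footprint_scores_zero(self):
        fp, ctl = _tracks([0, 0, 5], [5, 5, 5])
        sp = enrichment_score_profile(fp, ctl, CallerConfig())
        arr = sp.array("chr1", Strand.PLUS)
        assert arr[0] == 0 and arr[1] == 0 and arr[2] > 0

    def test_equal_counts_value_from_tail_summation(self):
        # f=5, c=5, r=1: P(X>=5 | lam=5) = 0.55951, score ~= 0.25219
        fp, ctl = _tracks([5], [5])
        sp = enrichment_score_profile(fp, ctl, CallerConfig())
        assert sp.array("chr1", Strand.PLUS)[0] == pytest.approx(
            0.2521946969075262, rel=1e-10
        )

    def test_pseudocount_floor_over_zero_control(self):
        # f=10, c=0, lambda_min=0.5: tail of Poisson(0.5) at 10
        fp, ctl = _tracks([10], [0])
        sp = enrichment_score_profile(fp, ctl, CallerConfig(lambda_min=0.5))
        assert sp.array("chr1", Strand.PLUS)[0] == pytest.approx(
            9.767087701456461, rel=1e-10
        )

    def test_matches_arbitrary_precision_oracle_on_spot_grid(self):
        lams = [0.5, 2.0, 10.0]
        fs = np.array([1, 3, 10, 40, 120])
        for lam in lams:
            got = poisson_enrichment_score(fs, np.full(fs.shape, lam))
            for f, g in zip(fs, got):
                want = float(oracles.poisson_tail_neglog10(int(f), lam))
                if want >= SCORE_CAP:
                    assert g == SCORE_CAP
                else:
                    assert g == pytest.approx(want, rel=1e-9)

    def test_monotone_in_footprint_depth_at_fixed_rate(self):
        f = np.arange(1, 100)
        s = poisson_enrichment_score(f, np.full(f.shape, 5.0))
        assert np.all(np.diff(s) > 0)

    def test_capped_and_finite(self):
        s = poisson_enrichment_score(np.array([5000.0]), np.array([0.5]))
        assert s[0] == SCORE_CAP

    def test_zero_library_size_rejected(self):
        fp, ctl = _tracks([1], [1], n_fp=0)
        with pytest.raises(ValueError):
            enrichment_score_profile(fp, ctl, CallerConfig())


def _profile(scores):
    arr = np.asarray(scores, dtype=float)
    return ScoreProfile({("chr1", Strand.PLUS): arr})


class TestSegmentation:
    def test_simple_run(self):
        sp = _profile([0, 0, 3, 3, 3, 0, 0, 0])
        cfg = CallerConfig(min_length=3)
        (r,) = segment_regions(sp, 2.0, cfg)
        assert (r.interval.start, r.interval.end) == (2, 5)
        assert r.score == 3.0

    def test_gap_merge_rescues_short_runs(self):
        scores = [0.0] * 3 + [5.0] * 8 + [0.0] + [5.0] * 8 + [0.0] * 3
        cfg = CallerConfig(min_length=15, max_gap=1)
        (r,) = segment_regions(_profile(scores), 2.0, cfg)
        assert r.interval.length == 17
        cfg0 = CallerConfig(min_length=15, max_gap=0)
        assert segment_regions(_profile(scores), 2.0, cfg0) == []

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            vals = rng.choice([0.0, 1.0, 2.0, 5.0], size=80, p=[0.5, 0.2, 0.2, 0.1])
            max_gap = int(rng.integers(0, 4))
            min_run = int(rng.integers(1, 8))
            thr = float(rng.choice([0.5, 1.0, 2.0]))
            got = [
                (r.interval.start, r.interval.end)
                for r in segment_regions(
                    _profile(vals), thr, CallerConfig(min_length=min_run, max_gap=max_gap)
                )
            ]
            assert got == oracles.brute_segments(vals, thr, max_gap, min_run)


def _split_library(rng, n_reads=2000, n_fp=400, length=2000):
    reads = [
        AlignedSegment("chr1", ((int(s), int(s) + 40),), Strand.PLUS)
        for s in rng.integers(0, length, size=n_reads)
    ]
    fp = Library("fp", "footprint", reads[:n_fp])
    ctl = Library("ctl", "control", reads[n_fp:])
    return fp, ctl


class TestPermutationFDR:
    def test_exchangeable_split_has_fdr_near_one(self):
        # footprint and control drawn from one pooled multiset: the
        # estimated FDR at low thresholds should sit near (or above) 1
        rng = np.random.default_rng(23)
        fp, ctl = _split_library(rng)
        table = permutation_fdr(fp, ctl, CallerConfig(seed=5))
        assert table.rows, "expected a populated FDR grid"
        assert table.rows[0].estimated_fdr > 0.5

    def test_single_permutation_is_deterministic(self):
        rng = np.random.default_rng(29)
        fp, ctl = _split_library(rng, n_reads=800, n_fp=200)
        cfg = CallerConfig(n_permutations=1, seed=11)
        t1 = permutation_fdr(fp, ctl, cfg)
        t2 = permutation_fdr(fp, ctl, cfg)
        assert t1.rows == t2.rows

    def test_fdr_is_monotone_non_increasing(self, standard_sim):
        _, _, _, fp, ctl = standard_sim
        table = permutation_fdr(fp, ctl, CallerConfig(seed=31))
        fdrs = [r.estimated_fdr for r in table.rows]
        assert all(a >= b for a, b in zip(fdrs, fdrs[1:]))

    def test_planted_enrichment_drives_fdr_to_zero(self, standard_sim):
        _, _, _, fp, ctl = standard_sim
        table = permutation_fdr(fp, ctl, CallerConfig(seed=37))
        assert table.rows[-1].estimated_fdr == 0.0


class TestCalling:
    def test_empty_footprint_returns_empty(self):
        ctl = Library(
            "ctl", "control", [AlignedSegment("chr1", ((0, 40),), Strand.PLUS)]
        )
        calls, table = call_pps(Library("fp", "footprint", []), ctl, CallerConfig())
        assert calls == [] and table.rows == []

    def test_planted_sites_recovered(self, standard_sim, standard_calls):
        _, _, truth, _, _ = standard_sim
        calls, _ = standard_calls
        rec = evaluate_recovery(calls, truth, min_overlap=0.5)
        assert rec.sensitivity >= 0.9
        assert rec.empirical_fdr is not None and rec.empirical_fdr <= 0.08

    def test_calls_carry_read_counts_and_threshold(self, standard_calls):
        calls, table = standard_calls
        thr = table.working_threshold(0.05)
        for c in calls:
            assert c.fdr_threshold_used == thr
            assert c.score >= thr
            assert c.footprint_reads > 0
            assert c.interval.length >= 15

    def test_plus_strand_scores_invariant_to_minus_strand_coverage(self):
        # at fixed library sizes (the depth ratio is global), minus-strand
        # reads cannot perturb plus-strand scores or segmentation
        rng = np.random.default_rng(43)
        f_plus = rng.integers(0, 20, size=300)
        c_plus = rng.integers(1, 20, size=300)
        key_p, key_m = ("chr1", Strand.PLUS), ("chr1", Strand.MINUS)
        cfg = CallerConfig(min_length=5)
        base = enrichment_score_profile(
            CoverageTrack({key_p: f_plus, key_m: np.zeros(300, int)}, 500),
            CoverageTrack({key_p: c_plus, key_m: np.zeros(300, int)}, 500),
            cfg,
        )
        noisy = enrichment_score_profile(
            CoverageTrack({key_p: f_plus, key_m: rng.integers(0, 30, 300)}, 500),
            CoverageTrack({key_p: c_plus, key_m: rng.integers(0, 30, 300)}, 500),
            cfg,
        )
        assert np.array_equal(base.array("chr1", Strand.PLUS), noisy.array("chr1", Strand.PLUS))
        seg_base = [
            (r.interval.start, r.interval.end)
            for r in segment_regions(base, 1.0, cfg)
            if r.interval.strand is Strand.PLUS
        ]
        seg_noisy = [
            (r.interval.start, r.interval.end)
            for r in segment_regions(noisy, 1.0, cfg)
            if r.interval.strand is Strand.PLUS
        ]
        assert seg_base == seg_noisy


class TestSaturation:
    def test_full_fraction_equals_full_call(self, standard_sim, standard_calls):
        _, _, _, fp, ctl = standard_sim
        calls, _ = standard_calls
        cfg = CallerConfig(seed=107)
        curve = saturation_curve(fp, ctl, [1.0], cfg)
        full_calls, _ = call_pps(fp, ctl, cfg)
        assert curve == [(1.0, len(full_calls))]

    def test_empty_fraction_list(self, standard_sim):
        _, _, _, fp, ctl = standard_sim
        assert saturation_curve(fp, ctl, [], CallerConfig()) == []

    def test_invalid_fraction_rejected(self, standard_sim):
        _, _, _, fp, ctl = standard_sim
        with pytest.raises(ValueError):
            saturation_curve(fp, ctl, [0.0], CallerConfig())
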