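"""Greedy annotation and its summary statistics."""
import numpy as np
import pytest

import oracles
from pipseq.annotate import (
    annotate_pps,
    coverage_fraction_comparison,
    expression_dependence,
    pps_size_stats,
    regional_density,
    summarize_annotations,
    transcript_read_counts,
)
from pipseq.caller import PPS
from pipseq.coverage import AlignedSegment, Library
from pipseq.model import GenomicInterval, RegionClass, RegionMap, Strand, Transcript, build_region_map


def _pps(chrom, start, end, strand=Strand.PLUS, score=10.0):
    return PPS(GenomicInterval(chrom, start, end, strand), score, score, 5, 5, 1.0)


def _region_map(entries):
    rm = RegionMap()
    grouped = {}
    for tx, iv, cls in entries:
        grouped.setdefault(tx, []).append((iv, cls))
    for tx, labeled in grouped.items():
        rm.add(tx, labeled)
    return rm


def test_single_isoform_cds_label():
    rm = _region_map(
        [("tx1", GenomicInterval("chr1", 0, 500, Strand.PLUS), RegionClass.CDS)]
    )
    (ann,) = annotate_pps([_pps("chr1", 100, 140)], rm)
    assert ann.labels == {(RegionClass.CDS, "tx1")}


def test_exon_intron_boundary_carries_both_labels():
    rm = _region_map(
        [
            ("tx1", GenomicInterval("chr1", 0, 200, Strand.PLUS), RegionClass.CDS),
            ("tx1", GenomicInterval("chr1", 200, 700, Strand.PLUS), RegionClass.INTRON_PROXIMAL),
        ]
    )
    (ann,) = annotate_pps([_pps("chr1", 180, 220)], rm)
    assert ann.labels == {
        (RegionClass.CDS, "tx1"),
        (RegionClass.INTRON_PROXIMAL, "tx1"),
    }


def test_unannotated_chromosome_falls_back_to_noncoding():
    rm = _region_map(
        [("tx1", GenomicInterval("chr1", 0, 100, Strand.PLUS), RegionClass.CDS)]
    )
    (ann,) = annotate_pps([_pps("chr9", 10, 50)], rm)
    assert ann.labels == {(RegionClass.NONCODING_OTHER, "")}


def _random_fixture(rng, n_pps=12, n_regions=20):
    classes = list(RegionClass)
    entries = []
    for i in range(n_regions):
        s = int(rng.integers(0, 900))
        e = s + int(rng.integers(20, 120))
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        entries.append(
            (
                f"tx{rng.integers(0, 6)}",
                GenomicInterval("chr1", s, e, strand),
                classes[int(rng.integers(0, len(classes)))],
            )
        )
    pps = []
    for _ in range(n_pps):
        s = int(rng.integers(0, 950))
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        pps.append(_pps("chr1", s, s + int(rng.integers(15, 60)), strand))
    return pps, entries


def test_labels_match_brute_force_all_pairs_scan():
    rng = np.random.default_rng(71)
    for _ in range(50):
        pps, entries = _random_fixture(rng)
        rm = _region_map(entries)
        got = [a.labels for a in annotate_pps(pps, rm)]
        want = oracles.brute_annotate([p.interval for p in pps], [(tx, iv, cls) for tx, iv, cls in entries])
        want = [w if w else {(RegionClass.NONCODING_OTHER, "")} for w in want]
        assert got == want


def test_absolute_distribution_counts_labels_not_pps():
    rm = _region_map(
        [
            ("txA", GenomicInterval("chr1", 0, 200, Strand.PLUS), RegionClass.CDS),
            ("txB", GenomicInterval("chr1", 0, 200, Strand.PLUS), RegionClass.UTR3),
        ]
    )
    anns = annotate_pps([_pps("chr1", 50, 90)], rm)
    transcripts = [
        Transcript("txA", "g", "mRNA", "chr1", Strand.PLUS, ((0, 200),), (0, 200)),
        Transcript("txB", "g", "mRNA", "chr1", Strand.PLUS, ((0, 200),), (0, 200)),
    ]
    summary = summarize_annotations(anns, transcripts, rm)
    assert sum(summary.absolute_distribution.values()) == 2
    assert summary.fraction_transcripts_with_pps == 1.0


def test_all_intronic_leaves_exonic_classes_at_zero():
    rm = _region_map(
        [
            ("tx1", GenomicInterval("chr1", 0, 100, Strand.PLUS), RegionClass.CDS),
            ("tx1", GenomicInterval("chr1", 100, 600, Strand.PLUS), RegionClass.INTRON_DISTAL),
        ]
    )
    anns = annotate_pps([_pps("chr1", 200, 240), _pps("chr1", 400, 440)], rm)
    transcripts = [
        Transcript("tx1", "g", "mRNA", "chr1", Strand.PLUS, ((0, 100),), (0, 100))
    ]
    summary = summarize_annotations(anns, transcripts, rm)
    assert summary.absolute_distribution.get(RegionClass.CDS, 0) == 0
    assert summary.absolute_distribution[RegionClass.INTRON_DISTAL] == 2


def test_regional_density_arithmetic_and_missing():
    rm = _region_map(
        [
            ("tx1", GenomicInterval("chr1", 0, 1000, Strand.PLUS), RegionClass.CDS),
            ("tx1", GenomicInterval("chr1", 2000, 3000, Strand.PLUS), RegionClass.UTR3),
        ]
    )
    pps = [_pps("chr1", 100, 200)]  # 100 nt inside CDS
    reads = [AlignedSegment("chr1", ((i * 15, i * 15 + 10),), Strand.PLUS) for i in range(50)]
    ctl = Library("ctl", "control", reads)  # 50 reads, all inside the CDS region
    dens = regional_density(pps, rm, ctl)
    assert dens[RegionClass.CDS].pps_base_coverage == 100
    assert dens[RegionClass.CDS].control_read_count == 50
    assert dens[RegionClass.CDS].density == pytest.approx(2.0)
    assert dens[RegionClass.UTR3].control_read_count == 0
    assert dens[RegionClass.UTR3].density is None


def test_density_invariant_to_coordinate_translation():
    def build(shift):
        rm = _region_map(
            [("tx1", GenomicInterval("chr1", shift, shift + 500, Strand.PLUS), RegionClass.CDS)]
        )
        pps = [_pps("chr1", shift + 10, shift + 60)]
        ctl = Library(
            "ctl",
            "control",
            [AlignedSegment("chr1", ((shift + 5, shift + 45),), Strand.PLUS)] * 4,
        )
        d = regional_density(pps, rm, ctl)[RegionClass.CDS]
        return d.pps_base_coverage, d.control_read_count, d.density

    assert build(0) == build(12345)


def test_size_stats_median():
    pps = [_pps("chr1", 0, 30), _pps("chr1", 100, 140), _pps("chr1", 200, 250)]
    stats = pps_size_stats(pps)
    assert stats.median == 40
    assert stats.histogram == {30: 1, 40: 1, 50: 1}
    assert pps_size_stats([_pps("chr1", 0, 27)]).median == 27


def test_expression_dependence_r_squared():
    expr = {f"t{i}": 10.0**i for i in range(6)}
    linear = {t: 2.0 * np.log10(v + 1) + 1 for t, v in expr.items()}
    assert expression_dependence(linear, expr) == pytest.approx(1.0, abs=1e-12)
    constant = {f"t{i}": 3 for i in range(6)}
    assert expression_dependence(constant, expr) == 0.0
    # closed form 1 - SSres/SStot on a noisy fixture
    rng = np.random.default_rng(5)
    x = np.log10(np.array([expr[f"t{i}"] for i in range(6)]) + 1)
    y = 2 * x + rng.normal(0, 1, size=6)
    counts = {f"t{i}": y[i] for i in range(6)}
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = ((y - (slope * x + intercept)) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    assert expression_dependence(counts, expr) == pytest.approx(1 - ss_res / ss_tot)


def _lnc_utr3_setup():
    lnc = Transcript("lnc1", "g1", "lncRNA", "chr1", Strand.PLUS, ((0, 200),), None)
    mrna = Transcript(
        "m1", "g2", "mRNA", "chr1", Strand.PLUS, ((1000, 1400),), (1000, 1200)
    )
    transcripts = [lnc, mrna]
    regions = build_region_map(transcripts)
    expr = {"lnc1": 50.0, "m1": 55.0}
    return transcripts, regions, expr


def test_coverage_fraction_full_and_empty():
    transcripts, regions, expr = _lnc_utr3_setup()
    full = [_pps("chr1", 0, 200)]
    lnc_frac, utr3_frac, pairs = coverage_fraction_comparison(
        transcripts, expr, full, regions, n_top=1
    )
    assert lnc_frac == 1.0 and utr3_frac == 0.0
    assert pairs == [("lnc1", "m1")]
    lnc0, utr0, _ = coverage_fraction_comparison(transcripts, expr, [], regions, n_top=1)
    assert lnc0 == 0.0 and utr0 == 0.0


def test_transcript_read_counts_as_expression_proxy():
    transcripts, regions, _ = _lnc_utr3_setup()
    reads = [AlignedSegment("chr1", ((10, 60),), Strand.PLUS)] * 3 + [
        AlignedSegment("chr1", ((1100, 1150),), Strand.PLUS)
    ]
    counts = transcript_read_counts(Library("ctl", "control", reads), transcripts)
    assert counts == {"lnc1": 3, "m1": 1}
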