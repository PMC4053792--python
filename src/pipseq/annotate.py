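"""Greedy functional annotation of PPSs and the summary statistics built on it.

Annotation is 'greedy': a PPS receives every (region class, transcript)
label whose territory it overlaps by at least one base on the same strand,
so one PPS overlapping a CDS in one isoform and a 3'UTR in another carries
both labels and is counted in both classes.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .caller import PPS
from .coverage import Library
from .model import (
    GenomicInterval,
    RegionClass,
    RegionMap,
    Strand,
    Transcript,
    merged_by_key,
    overlap_with_merged,
)

log = logging.getLogger(__name__)


@dataclass
class PPSAnnotation:
    pps_id: int
    pps: PPS
    labels: set[tuple[RegionClass, str]] = field(default_factory=set)


def annotate_pps(pps_list: Sequence[PPS], regions: RegionMap) -> list[PPSAnnotation]:
    """Attach every overlapping (RegionClass, transcript) pair to each PPS.

    A PPS overlapping nothing in the annotation (including PPSs on
    chromosomes absent from it) is labeled ``(noncoding_other, "")``.
    """
    trees: dict[tuple[str, Strand], IntervalTree] = defaultdict(IntervalTree)
    for tx_id, iv, cls in regions:
        trees[(iv.chrom, iv.strand)].addi(iv.start, iv.end, (cls, tx_id))
    out: list[PPSAnnotation] = []
    for i, p in enumerate(pps_list):
        iv = p.interval if isinstance(p, PPS) else p
        hits = trees.get((iv.chrom, iv.strand), IntervalTree()).overlap(iv.start, iv.end)
        labels = {h.data for h in hits}
        if not labels:
            labels = {(RegionClass.NONCODING_OTHER, "")}
        out.append(PPSAnnotation(pps_id=i, pps=p, labels=labels))
    return out


@dataclass
class AnnotationSummary:
    """Label-level distribution and per-transcript PPS counts.

    ``absolute_distribution`` totals the labels (not the PPSs: greedy
    double counting is by design).  Per-region means come in two flavours:
    over transcripts carrying >= 1 PPS in that region (default reading) and
    over all transcripts exposing the region.
    """

    absolute_distribution: dict[RegionClass, int]
    mean_count_per_region: dict[RegionClass, float]
    mean_count_per_region_all: dict[RegionClass, float]
    fraction_with_pps_per_region: dict[RegionClass, float]
    fraction_transcripts_with_pps: float


def summarize_annotations(
    annotations: Sequence[PPSAnnotation], transcripts: Sequence[Transcript], regions: RegionMap
) -> AnnotationSummary:
    absolute: Counter = Counter()
    per_tx_region: Counter = Counter()  # (tx, class) -> n PPSs
    for ann in annotations:
        for cls, tx in ann.labels:
            absolute[cls] += 1
            if tx:
                per_tx_region[(tx, cls)] += 1

    region_exposure: dict[RegionClass, set[str]] = defaultdict(set)
    for tx_id, _, cls in regions:
        region_exposure[cls].add(tx_id)

    mean_with: dict[RegionClass, float] = {}
    mean_all: dict[RegionClass, float] = {}
    frac: dict[RegionClass, float] = {}
    for cls in RegionClass:
        exposing = region_exposure.get(cls, set())
        counts = {tx: n for (tx, c), n in per_tx_region.items() if c is cls}
        if counts:
            mean_with[cls] = float(np.mean(list(counts.values())))
        if exposing:
            mean_all[cls] = sum(counts.values()) / len(exposing)
            frac[cls] = len(counts) / len(exposing)

    with_pps = {tx for (tx, _), n in per_tx_region.items() if n > 0}
    frac_any = len(with_pps) / len(transcripts) if transcripts else 0.0
    return AnnotationSummary(
        absolute_distribution=dict(absolute),
        mean_count_per_region=mean_with,
        mean_count_per_region_all=mean_all,
        fraction_with_pps_per_region=frac,
        fraction_transcripts_with_pps=frac_any,
    )


@dataclass
class RegionDensity:
    region_class: RegionClass
    pps_base_coverage: int
    control_read_count: int
    density: float | None  # None when no control reads fall in the region


def regional_density(
    pps_list: Sequence[PPS], regions: RegionMap, ctl: Library
) -> dict[RegionClass, RegionDensity]:
    """PPS base coverage normalized to control read counts per region class."""
    pps_merged = merged_by_key(p.interval for p in pps_list)
    out: dict[RegionClass, RegionDensity] = {}
    for cls in RegionClass:
        territory = merged_by_key(iv for _, iv, c in regions if c is cls)
        if not territory:
            continue
        base_cov = 0
        for key, merged in territory.items():
            pm = pps_merged.get(key, [])
            for s, e in merged:
                base_cov += overlap_with_merged(pm, s, e)
        n_reads = 0
        for r in ctl.reads:
            merged = territory.get((r.chrom, r.strand), [])
            if merged and any(overlap_with_merged(merged, s, e) > 0 for s, e in r.blocks):
                n_reads += 1
        density = base_cov / n_reads if n_reads > 0 else None
        if density is None:
            log.info("region class %s has zero control reads; density missing", cls.value)
        out[cls] = RegionDensity(cls, base_cov, n_reads, density)
    return out


@dataclass
class SizeStats:
    median: float
    histogram: dict[int, int]


def pps_size_stats(pps_list: Sequence[PPS]) -> SizeStats:
    """Median PPS length and a 1-nt-resolution length histogram."""
    if not pps_list:
        raise ValueError("no PPSs")
    lengths = [p.length for p in pps_list]
    return SizeStats(median=float(np.median(lengths)), histogram=dict(Counter(lengths)))


def transcript_read_counts(lib: Library, transcripts: Sequence[Transcript]) -> dict[str, int]:
    """Reads per transcript exonic territory — the expression proxy."""
    trees: dict[tuple[str, Strand], IntervalTree] = defaultdict(IntervalTree)
    for t in transcripts:
        for s, e in t.exons:
            trees[(t.chrom, t.strand)].addi(s, e, t.id)
    counts: Counter = Counter({t.id: 0 for t in transcripts})
    for r in lib.reads:
        tree = trees.get((r.chrom, r.strand))
        if tree is None:
            continue
        hit_tx = set()
        for s, e in r.blocks:
            hit_tx.update(h.data for h in tree.overlap(s, e))
        for tx in hit_tx:
            counts[tx] += 1
    return dict(counts)


def expression_dependence(
    pps_counts: Mapping[str, int], expression: Mapping[str, float]
) -> float:
    """R^2 of the OLS fit of per-transcript PPS count on log10(expression + 1)."""
    tx = sorted(set(pps_counts) & set(expression))
    if len(tx) < 3:
        raise ValueError("need >= 3 transcripts with both counts and expression")
    y = np.array([pps_counts[t] for t in tx], dtype=float)
    x = np.log10(np.array([expression[t] for t in tx], dtype=float) + 1.0)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    var_x = float(((x - x.mean()) ** 2).sum())
    slope = float(((x - x.mean()) * (y - y.mean())).sum()) / var_x if var_x > 0 else 0.0
    resid = y - (y.mean() + slope * (x - x.mean()))
    return 1.0 - float((resid**2).sum()) / ss_tot


def coverage_fraction_comparison(
    transcripts: Sequence[Transcript],
    expression: Mapping[str, float],
    pps_list: Sequence[PPS],
    regions: RegionMap,
    n_top: int = 100,
) -> tuple[float, float, list[tuple[str, str]]]:
    """Fraction of bases PPS-covered in top-expressed lncRNAs vs
    expression-matched mRNA 3'UTRs.

    The ``n_top`` highest-expression lncRNAs are each matched greedily to
    the unused mRNA whose expression is nearest; coverage is measured over
    lncRNA exons and matched 3'UTR territory respectively.
    """
    lncs = sorted(
        (t for t in transcripts if t.biotype == "lncRNA" and t.id in expression),
        key=lambda t: -expression[t.id],
    )[:n_top]
    utr3_by_tx = {
        t.id: [iv for iv, c in regions.regions.get(t.id, []) if c is RegionClass.UTR3]
        for t in transcripts
        if t.biotype == "mRNA"
    }
    candidates = sorted(
        (tx for tx, ivs in utr3_by_tx.items() if ivs and tx in expression),
        key=lambda tx: expression[tx],
    )
    if not lncs or not candidates:
        raise ValueError("need both expressed lncRNAs and mRNA 3'UTRs")

    pps_merged = merged_by_key(p.interval for p in pps_list)
    pairs: list[tuple[str, str]] = []
    used: set[str] = set()
    cand_expr = [expression[tx] for tx in candidates]
    for lnc in lncs:
        best, best_d = None, float("inf")
        for tx, ex in zip(candidates, cand_expr):
            if tx in used:
                continue
            d = abs(ex - expression[lnc.id])
            if d < best_d:
                best, best_d = tx, d
        if best is None:
            break
        used.add(best)
        pairs.append((lnc.id, best))

    def group_fraction(interval_lists: Iterable[list[GenomicInterval]]) -> float:
        covered = total = 0
        for ivs in interval_lists:
            for iv in ivs:
                total += iv.length
                covered += overlap_with_merged(
                    pps_merged.get((iv.chrom, iv.strand), []), iv.start, iv.end
                )
        return covered / total if total else 0.0

    lnc_fraction = group_fraction([t.exon_intervals() for t in lncs])
    utr3_fraction = group_fraction([utr3_by_tx[tx] for _, tx in pairs])
    return lnc_fraction, utr3_fraction, pairs
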