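"""Overlap enrichment of PPSs against external interval sets.

The background model is a size-preserving shuffle: random interval sets
with the same length multiset as the PPSs, placed uniformly inside the
actively transcribed segments of the control library (run/gap/min-run
segmentation of control coverage, default threshold=10, maxGap=10,
minRun=15).  Significance comes from a chi-squared test on the 2x2 table
of overlapping vs non-overlapping intervals, observed vs pooled shuffles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .caller import PPS
from .coverage import CoverageTrack
from .model import GenomicInterval, merged_by_key, overlap_with_merged
from .segmentation import segment_above_threshold

log = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """2x2 counts; chi-squared (1 df, no continuity correction) on demand."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (self.table < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if self.table.sum() == 0:
            raise ValueError("contingency table is empty")

    def chi_squared(self) -> tuple[float, float]:
        """(statistic, p); a degenerate table (zero marginal) gives (0, 1)."""
        if (self.table.sum(axis=0) == 0).any() or (self.table.sum(axis=1) == 0).any():
            return 0.0, 1.0
        res = stats.chi2_contingency(self.table, correction=False)
        return float(res.statistic), float(res.pvalue)


@dataclass
class BackgroundSegments:
    """Actively transcribed regions used as the shuffle background."""

    segments: list[GenomicInterval]
    threshold: float
    max_gap: int
    min_run: int


def segment_transcribed_regions(
    ctl: CoverageTrack, threshold: float = 10, max_gap: int = 10, min_run: int = 15
) -> BackgroundSegments:
    """Maximal runs of control coverage >= threshold, gap-merged and
    length-filtered, per chromosome and strand."""
    if threshold <= 0 or max_gap < 0 or min_run < 1:
        raise ValueError("segmentation parameters must be positive")
    segs: list[GenomicInterval] = []
    for (chrom, strand), arr in sorted(ctl.data.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        for s, e in segment_above_threshold(arr, threshold, max_gap, min_run):
            segs.append(GenomicInterval(chrom, s, e, strand))
    return BackgroundSegments(segs, threshold, max_gap, min_run)


def shuffle_intervals(
    sizes: Sequence[int],
    background: BackgroundSegments,
    n_sets: int = 10,
    seed: int = 0,
) -> list[list[GenomicInterval]]:
    """Random interval sets with the given length multiset inside the background.

    Each interval is placed fully inside a background segment, the segment
    drawn with probability proportional to its number of valid start
    positions.  An interval longer than every segment is anchored at the
    start of the largest segment and logged.
    """
    if not background.segments:
        raise ValueError("empty background")
    rng = np.random.default_rng(seed)
    seg_lens = np.array([s.length for s in background.segments])
    out: list[list[GenomicInterval]] = []
    for _ in range(n_sets):
        placed: list[GenomicInterval] = []
        for size in sizes:
            valid = np.maximum(0, seg_lens - size + 1)
            total = valid.sum()
            if total == 0:
                seg = background.segments[int(np.argmax(seg_lens))]
                log.warning("interval of length %d exceeds every background segment", size)
                placed.append(GenomicInterval(seg.chrom, seg.start, seg.start + size, seg.strand))
                continue
            seg_idx = rng.choice(len(seg_lens), p=valid / total)
            seg = background.segments[seg_idx]
            start = seg.start + int(rng.integers(0, valid[seg_idx]))
            placed.append(GenomicInterval(seg.chrom, start, start + size, seg.strand))
        out.append(placed)
    return out


def _count_overlapping(
    query: Sequence[GenomicInterval], subject_merged: dict, stranded: bool
) -> int:
    n = 0
    for iv in query:
        key = (iv.chrom, iv.strand if stranded else None)
        if overlap_with_merged(subject_merged.get(key, []), iv.start, iv.end) > 0:
            n += 1
    return n


@dataclass
class OverlapEnrichment:
    observed: int
    expected: float
    log2_enrichment: float | None
    table: ContingencyTable
    chi_squared: float
    p_value: float


def overlap_enrichment(
    query: Sequence, subject: Sequence[GenomicInterval], shuffles: list[list[GenomicInterval]]
) -> OverlapEnrichment:
    """log2 enrichment of query-vs-subject overlap over shuffled backgrounds.

    The overlap unit is the query interval (>= 1 nt of overlap counts it
    once); strand is respected when both query and subject carry strands.
    The contingency table pools all shuffle sets as the background row.
    """
    if not shuffles:
        raise ValueError("need at least one shuffle set")
    query_ivs = [p.interval if isinstance(p, PPS) else p for p in query]
    stranded = all(iv.strand is not None for iv in query_ivs) and all(
        iv.strand is not None for iv in subject
    )
    if not stranded:
        subject_merged = merged_by_key(iv.unstranded() for iv in subject)
    else:
        subject_merged = merged_by_key(subject)
    observed = _count_overlapping(
        query_ivs if stranded else [iv.unstranded() for iv in query_ivs],
        subject_merged,
        stranded,
    )
    shuffle_hits = [
        _count_overlapping(
            s if stranded else [iv.unstranded() for iv in s], subject_merged, stranded
        )
        for s in shuffles
    ]
    expected = float(np.mean(shuffle_hits))
    log2_enr = float(np.log2(observed / expected)) if expected > 0 and observed > 0 else None
    n_pool = sum(len(s) for s in shuffles)
    pooled_hits = sum(shuffle_hits)
    table = ContingencyTable(
        [[observed, len(query_ivs) - observed], [pooled_hits, n_pool - pooled_hits]]
    )
    chi2, p = table.chi_squared()
    return OverlapEnrichment(observed, expected, log2_enr, table, chi2, p)


def merge_nearby_events(
    events: Sequence[GenomicInterval], max_dist: int = 40
) -> list[GenomicInterval]:
    """Single-linkage merge of events closer than ``max_dist``.

    Distance between two clusters is measured between their closest
    contained positions, so point events at 100 and 130 (30 apart) merge
    into [100, 131) while events 40 or more apart stay separate.  The
    operation is idempotent on its own output.
    """
    grouped: dict = {}
    for ev in events:
        grouped.setdefault((ev.chrom, ev.strand), []).append((ev.start, ev.end))
    out: list[GenomicInterval] = []
    for (chrom, strand), ivs in sorted(grouped.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s - cur_e + 1 < max_dist:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    return out


@dataclass
class EventsPerInterval:
    counts: np.ndarray  # events contained per query interval
    histogram: dict[int, int]
    mean: float
    shuffled_mean: float | None


def events_per_interval(
    pps: Sequence,
    events: Sequence[GenomicInterval],
    shuffles: list[list[GenomicInterval]] | None = None,
) -> EventsPerInterval:
    """Events contained per PPS, with the mean per-interval count over the
    shuffle sets as the baseline."""
    query = [p.interval if isinstance(p, PPS) else p for p in pps]
    positions: dict = {}
    for ev in events:
        positions.setdefault(ev.chrom, []).append(ev.start)
    for v in positions.values():
        v.sort()

    def count_in(ivs: Sequence[GenomicInterval]) -> np.ndarray:
        res = np.zeros(len(ivs), dtype=np.int64)
        for i, iv in enumerate(ivs):
            pos = positions.get(iv.chrom, [])
            res[i] = np.searchsorted(pos, iv.end, side="left") - np.searchsorted(
                pos, iv.start, side="left"
            )
        return res

    counts = count_in(query)
    hist: dict[int, int] = {}
    for c in counts.tolist():
        hist[c] = hist.get(c, 0) + 1
    shuffled_mean = None
    if shuffles:
        shuffled_mean = float(np.mean([count_in(s).mean() if s else 0.0 for s in shuffles]))
    mean = float(counts.mean()) if counts.size else 0.0
    return EventsPerInterval(counts, hist, mean, shuffled_mean)
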