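"""Aligned reads to strand-specific per-base coverage.

A library is a bag of aligned segments (possibly spliced, i.e. multi-block)
from either the footprint or the RNase digestion control sample.  PCR
duplicates — reads with an identical block structure on the same strand —
are collapsed to a single representative before any counting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .model import GenomicInterval, Strand

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned read: ordered disjoint blocks on one chrom/strand."""

    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: Strand

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read with no aligned blocks")
        prev = -1
        for s, e in self.blocks:
            if not (0 <= s < e) or s < prev:
                raise ValueError(f"bad block structure: {self.blocks}")
            prev = e

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def flipped(self) -> "AlignedSegment":
        return replace(self, strand=self.strand.flipped())


@dataclass
class Library:
    """A named read collection with a fixed footprint/control role."""

    name: str
    role: str  # "footprint" or "control"
    reads: list[AlignedSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("footprint", "control"):
            raise ValueError(f"library role must be footprint/control, got {self.role!r}")

    @property
    def size(self) -> int:
        return len(self.reads)

    def chrom_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads:
            out[r.chrom] = max(out.get(r.chrom, 0), r.span[1])
        return out


@dataclass
class CoverageTrack:
    """Per-(chrom, strand) integer read-depth arrays plus the library size."""

    data: dict[tuple[str, Strand], np.ndarray]
    library_size: int

    def array(self, chrom: str, strand: Strand) -> np.ndarray:
        return self.data.get((chrom, strand), np.zeros(0, dtype=np.int64))

    def total_mass(self) -> int:
        return int(sum(arr.sum() for arr in self.data.values()))


def load_alignments(path: str | Path, dialect: str = "bam", strandedness: str = "forward") -> Library:
    """Load a BAM/SAM or BED alignment file into a Library.

    ``strandedness="reverse"`` flips every read's strand (for dUTP-style
    protocols whose reads land antisense to the transcript).  Unmapped,
    secondary and supplementary BAM records are skipped and counted.
    """
    if strandedness not in ("forward", "reverse"):
        raise ValueError("strandedness must be forward or reverse")
    if dialect == "bam":
        reads = _load_bam(path)
    elif dialect == "bed":
        reads = _load_bed_alignments(path)
    else:
        raise ValueError(f"unknown alignment dialect: {dialect!r}")
    if strandedness == "reverse":
        reads = [r.flipped() for r in reads]
    return Library(name=str(path), role="footprint", reads=reads)


def _load_bam(path: str | Path) -> list[AlignedSegment]:
    import pysam

    reads: list[AlignedSegment] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            blocks = _merge_adjacent(rec.get_blocks())
            strand = Strand.MINUS if rec.is_reverse else Strand.PLUS
            reads.append(AlignedSegment(rec.reference_name, tuple(blocks), strand))
    if skipped:
        log.info("skipped %d unmapped/secondary/supplementary records in %s", skipped, path)
    return reads


def _merge_adjacent(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Join abutting blocks (deletions split pysam blocks; splices should not)."""
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _load_bed_alignments(path: str | Path) -> list[AlignedSegment]:
    from .io import ParseError

    reads: list[AlignedSegment] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 6:
            raise ParseError(f"{path}:{i}: alignment BED needs >= 6 columns")
        chrom, start = f[0], int(f[1])
        strand = Strand.from_symbol(f[5])
        if len(f) >= 12:  # BED12: spliced blocks
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        else:
            blocks = ((start, int(f[2])),)
        reads.append(AlignedSegment(chrom, blocks, strand))
    return reads


def collapse_duplicates(lib: Library) -> Library:
    """Collapse PCR duplicates: identical (chrom, blocks, strand) keeps one read."""
    seen: set[AlignedSegment] = set()
    kept: list[AlignedSegment] = []
    for r in lib.reads:
        if r not in seen:
            seen.add(r)
            kept.append(r)
    return Library(name=lib.name, role=lib.role, reads=kept)


def compute_coverage(lib: Library, chrom_lengths: dict[str, int] | None = None) -> CoverageTrack:
    """Per-base, per-strand read depth; total mass equals total block length."""
    lengths = dict(chrom_lengths or {})
    for chrom, ln in lib.chrom_lengths().items():
        lengths[chrom] = max(lengths.get(chrom, 0), ln)

    starts: dict[tuple[str, Strand], list[int]] = {}
    ends: dict[tuple[str, Strand], list[int]] = {}
    for r in lib.reads:
        key = (r.chrom, r.strand)
        for s, e in r.blocks:
            starts.setdefault(key, []).append(s)
            ends.setdefault(key, []).append(e)

    data: dict[tuple[str, Strand], np.ndarray] = {}
    for chrom, ln in lengths.items():
        for strand in (Strand.PLUS, Strand.MINUS):
            diff = np.zeros(ln + 1, dtype=np.int64)
            key = (chrom, strand)
            if key in starts:
                np.add.at(diff, np.asarray(starts[key]), 1)
                np.add.at(diff, np.asarray(ends[key]), -1)
            data[key] = np.cumsum(diff[:-1])
    return CoverageTrack(data=data, library_size=lib.size)


def window_counts(
    track: CoverageTrack, window: int, step: int
) -> list[tuple[GenomicInterval, int]]:
    """Sliding-window coverage sums, tiled per chrom/strand (last window truncated)."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    out: list[tuple[GenomicInterval, int]] = []
    for (chrom, strand), arr in sorted(track.data.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        csum = np.concatenate(([0], np.cumsum(arr)))
        for start in range(0, len(arr), step):
            end = min(start + window, len(arr))
            out.append(
                (GenomicInterval(chrom, start, end, strand), int(csum[end] - csum[start]))
            )
    return out


def replicate_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation between paired window counts."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length count vectors of length >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance counts")
    return float(stats.pearsonr(a, b).statistic)


def subsample_alignments(lib: Library, fraction: float, seed: int) -> Library:
    """Sample round(fraction * size) reads without replacement, seeded."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = round(fraction * lib.size)
    rng = np.random.default_rng(seed)
    idx = rng.choice(lib.size, size=n, replace=False)
    idx.sort()
    return Library(name=lib.name, role=lib.role, reads=[lib.reads[i] for i in idx])


def reads_overlapping(lib: Library, interval: GenomicInterval) -> int:
    """Number of reads with >= 1 block overlapping the (stranded) interval."""
    n = 0
    for r in lib.reads:
        if r.chrom != interval.chrom:
            continue
        if interval.strand is not None and r.strand is not interval.strand:
            continue
        if any(s < interval.end and interval.start < e for s, e in r.blocks):
            n += 1
    return n
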