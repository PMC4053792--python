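"""Genomic coordinate types, gene models and genic-region decomposition.

All coordinates in this package are 0-based half-open (BED convention);
GTF input is converted at the parsing boundary.  The genic vocabulary used
throughout the downstream statistics is the :class:`RegionClass` enum:
5'UTR / CDS / 3'UTR for coding exons, proximal vs distal intron (within or
beyond ``proximal_nt`` of a splice site), lncRNA exons, and a catch-all
``noncoding_other``.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


class Strand(enum.Enum):
    """Transcription strand; all stranded operations mirror under a flip."""

    PLUS = "+"
    MINUS = "-"

    def flipped(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_symbol(cls, symbol: str) -> "Strand":
        if symbol == "+":
            return cls.PLUS
        if symbol == "-":
            return cls.MINUS
        raise ValueError(f"not a strand symbol: {symbol!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: Strand | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand is not None and other.strand is not None:
            if self.strand is not other.strand:
                return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval", stranded: bool = True) -> int:
        if not self.overlaps(other, stranded=stranded):
            return 0
        return min(self.end, other.end) - max(self.start, other.start)

    def unstranded(self) -> "GenomicInterval":
        return replace(self, strand=None)


class RegionClass(enum.Enum):
    """Closed vocabulary of genic region labels."""

    UTR5 = "utr5"
    CDS = "cds"
    UTR3 = "utr3"
    INTRON_PROXIMAL = "intron_proximal"
    INTRON_DISTAL = "intron_distal"
    LNCRNA_EXON = "lncRNA_exon"
    NONCODING_OTHER = "noncoding_other"


#: classes that live on exonic territory of coding transcripts
EXONIC_CLASSES = (RegionClass.UTR5, RegionClass.CDS, RegionClass.UTR3)
INTRONIC_CLASSES = (RegionClass.INTRON_PROXIMAL, RegionClass.INTRON_DISTAL)


@dataclass(frozen=True)
class Transcript:
    """A gene model: ordered disjoint exons plus an optional genomic CDS span.

    ``biotype`` is one of ``mRNA`` / ``lncRNA`` / ``other``; the CDS is only
    meaningful for mRNAs.  Exons are (start, end) pairs sorted along the
    genome regardless of strand.
    """

    id: str
    gene_id: str
    biotype: str
    chrom: str
    strand: Strand
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"transcript {self.id}: bad exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"transcript {self.id}: exons overlap or unsorted")
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if not (cs < ce):
                raise ValueError(f"transcript {self.id}: empty CDS span")
            if cs < self.exons[0][0] or ce > self.exons[-1][1]:
                raise ValueError(f"transcript {self.id}: CDS outside exon span")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0][0], self.exons[-1][1], self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.exons]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def flipped(self) -> "Transcript":
        """Same coordinates, opposite strand (used by symmetry checks)."""
        return replace(self, strand=self.strand.flipped())


@dataclass
class RegionMap:
    """Per-transcript genic-region labels over exonic and intronic territory."""

    regions: dict[str, list[tuple[GenomicInterval, RegionClass]]] = field(default_factory=dict)

    def add(self, transcript_id: str, labeled: list[tuple[GenomicInterval, RegionClass]]) -> None:
        self.regions[transcript_id] = labeled

    def __iter__(self) -> Iterator[tuple[str, GenomicInterval, RegionClass]]:
        for tx_id, labeled in self.regions.items():
            for iv, cls in labeled:
                yield tx_id, iv, cls

    def __len__(self) -> int:
        return len(self.regions)

    def intervals_of_class(self, cls: RegionClass) -> list[GenomicInterval]:
        return [iv for _, iv, c in self if c is cls]

    def territory(self, classes: Iterable[RegionClass] | None = None) -> dict[str, list[tuple[int, int]]]:
        """Merged unstranded territory per chromosome for the given classes."""
        wanted = set(classes) if classes is not None else None
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for _, iv, cls in self:
            if wanted is not None and cls not in wanted:
                continue
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: merge_interval_pairs(ivs) for c, ivs in per_chrom.items()}


def merge_interval_pairs(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) pairs as a sorted list of disjoint pairs."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merged_by_key(
    intervals: Iterable[GenomicInterval],
) -> dict[tuple[str, Strand | None], list[tuple[int, int]]]:
    """Group intervals by (chrom, strand) and merge each group."""
    grouped: dict[tuple[str, Strand | None], list[tuple[int, int]]] = {}
    for iv in intervals:
        grouped.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
    return {k: merge_interval_pairs(v) for k, v in grouped.items()}


def overlap_with_merged(merged: list[tuple[int, int]], start: int, end: int) -> int:
    """Overlap length of [start, end) with a sorted disjoint interval list."""
    from bisect import bisect_left, bisect_right

    if not merged:
        return 0
    starts = [s for s, _ in merged]
    lo = max(0, bisect_right(starts, start) - 1)
    hi = bisect_left(starts, end)
    total = 0
    for s, e in merged[lo:hi]:
        total += max(0, min(e, end) - max(s, start))
    return total


def subtract_merged(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a \\ b of two merged, sorted interval-pair lists."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _split_exon_by_cds(
    exon: tuple[int, int], cds: tuple[int, int], strand: Strand
) -> list[tuple[tuple[int, int], RegionClass]]:
    s, e = exon
    cs, ce = cds
    low_cls = RegionClass.UTR5 if strand is Strand.PLUS else RegionClass.UTR3
    high_cls = RegionClass.UTR3 if strand is Strand.PLUS else RegionClass.UTR5
    pieces: list[tuple[tuple[int, int], RegionClass]] = []
    if s < min(e, cs):
        pieces.append(((s, min(e, cs)), low_cls))
    if max(s, cs) < min(e, ce):
        pieces.append(((max(s, cs), min(e, ce)), RegionClass.CDS))
    if max(s, ce) < e:
        pieces.append(((max(s, ce), e), high_cls))
    return pieces


def decompose_transcript(
    t: Transcript, proximal_nt: int = 500
) -> list[tuple[GenomicInterval, RegionClass]]:
    """Label every exonic and intronic base of one transcript.

    Coding exons are split into 5'UTR / CDS / 3'UTR around the genomic CDS
    span (strand decides which side is which); each intron contributes its
    first and last ``proximal_nt`` bases as proximal intron and the remainder
    as distal intron (introns of length <= 2*proximal_nt are wholly
    proximal).  lncRNA exons are labeled as such; anything else exonic is
    ``noncoding_other``.  The result is a partition: labels never overlap
    within one transcript.
    """
    if proximal_nt <= 0:
        raise ValueError("proximal_nt must be positive")
    out: list[tuple[GenomicInterval, RegionClass]] = []

    if t.biotype == "mRNA" and t.cds is not None:
        for exon in t.exons:
            for (s, e), cls in _split_exon_by_cds(exon, t.cds, t.strand):
                out.append((GenomicInterval(t.chrom, s, e, t.strand), cls))
    elif t.biotype == "lncRNA":
        for s, e in t.exons:
            out.append((GenomicInterval(t.chrom, s, e, t.strand), RegionClass.LNCRNA_EXON))
    else:
        if t.biotype == "mRNA":
            warnings.warn(
                f"mRNA transcript {t.id} has no CDS; labeling exons noncoding_other"
            )
        for s, e in t.exons:
            out.append((GenomicInterval(t.chrom, s, e, t.strand), RegionClass.NONCODING_OTHER))

    for s, e in t.introns():
        length = e - s
        if length <= 2 * proximal_nt:
            out.append((GenomicInterval(t.chrom, s, e, t.strand), RegionClass.INTRON_PROXIMAL))
        else:
            out.append(
                (GenomicInterval(t.chrom, s, s + proximal_nt, t.strand), RegionClass.INTRON_PROXIMAL)
            )
            out.append(
                (GenomicInterval(t.chrom, s + proximal_nt, e - proximal_nt, t.strand), RegionClass.INTRON_DISTAL)
            )
            out.append(
                (GenomicInterval(t.chrom, e - proximal_nt, e, t.strand), RegionClass.INTRON_PROXIMAL)
            )
    out.sort(key=lambda p: (p[0].start, p[0].end))
    return out


def build_region_map(transcripts: Iterable[Transcript], proximal_nt: int = 500) -> RegionMap:
    rm = RegionMap()
    for t in transcripts:
        rm.add(t.id, decompose_transcript(t, proximal_nt=proximal_nt))
    return rm
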