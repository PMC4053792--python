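"""SNP enrichment within PPSs against genic-region-matched backgrounds.

The background for each SNP set is the territory of the same genic region
classes the PPSs fall in, with PPS bases excluded, so enrichment is judged
against comparably annotated (and comparably expressed) sequence rather
than the whole genome.  Counting is unstranded: a SNP has no strand.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .caller import PPS
from .enrichment import ContingencyTable
from .model import (
    GenomicInterval,
    RegionClass,
    RegionMap,
    merge_interval_pairs,
    overlap_with_merged,
    subtract_merged,
)


@dataclass(frozen=True)
class SNPRecord:
    """A single-base variant with a set label (e.g. flagged, gwas)."""

    position: GenomicInterval
    set_label: str
    functional_class: str | None = None  # synonymous / nonsynonymous / other

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError("SNP records must span exactly one base")


def _pps_merged_unstranded(pps_list: Sequence) -> dict[str, list[tuple[int, int]]]:
    grouped: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for p in pps_list:
        iv = p.interval if isinstance(p, PPS) else p
        grouped[iv.chrom].append((iv.start, iv.end))
    return {c: merge_interval_pairs(v) for c, v in grouped.items()}


def _matched_background(
    pps_list: Sequence, regions: RegionMap
) -> tuple[dict[str, list[tuple[int, int]]], dict[str, list[tuple[int, int]]]]:
    """(PPS bases, class-matched territory minus PPS bases), per chromosome."""
    pps_merged = _pps_merged_unstranded(pps_list)
    # which region classes do the PPSs actually occupy?
    classes: set[RegionClass] = set()
    by_class: dict[RegionClass, dict[str, list[tuple[int, int]]]] = {}
    for cls in RegionClass:
        terr: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for _, iv, c in regions:
            if c is cls:
                terr[iv.chrom].append((iv.start, iv.end))
        if terr:
            by_class[cls] = {ch: merge_interval_pairs(v) for ch, v in terr.items()}
    for cls, terr in by_class.items():
        for chrom, merged in terr.items():
            if any(
                overlap_with_merged(merged, s, e) > 0
                for s, e in pps_merged.get(chrom, [])
            ):
                classes.add(cls)
                break
    territory: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for cls in classes:
        for chrom, merged in by_class[cls].items():
            territory[chrom].extend(merged)
    background = {
        chrom: subtract_merged(merge_interval_pairs(v), pps_merged.get(chrom, []))
        for chrom, v in territory.items()
    }
    return pps_merged, background


def _total_length(merged: dict[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for v in merged.values() for s, e in v)


def _snps_in(snps: Sequence[SNPRecord], merged: dict[str, list[tuple[int, int]]]) -> list[SNPRecord]:
    return [
        s
        for s in snps
        if overlap_with_merged(merged.get(s.position.chrom, []), s.position.start, s.position.end) > 0
    ]


@dataclass
class SnpEnrichment:
    set_label: str
    observed: int
    background: int
    pps_bases: int
    background_bases: int
    fold_enrichment: float | None
    table: ContingencyTable
    chi_squared: float
    p_value: float


def snp_enrichment(
    snps: Sequence[SNPRecord], pps_list: Sequence, regions: RegionMap
) -> dict[str, SnpEnrichment]:
    """Per-set fold enrichment of SNP density in PPS bases over the matched
    background, with a chi-squared test on base counts."""
    pps_merged, background = _matched_background(pps_list, regions)
    pps_bases = _total_length(pps_merged)
    bg_bases = _total_length(background)
    out: dict[str, SnpEnrichment] = {}
    for label in sorted({s.set_label for s in snps}):
        subset = [s for s in snps if s.set_label == label]
        n_in = len(_snps_in(subset, pps_merged))
        n_bg = len(_snps_in(subset, background))
        table = ContingencyTable(
            [[n_in, max(0, pps_bases - n_in)], [n_bg, max(0, bg_bases - n_bg)]]
        )
        chi2, p = table.chi_squared()
        fold = None
        if pps_bases > 0 and bg_bases > 0 and n_bg > 0:
            fold = (n_in / pps_bases) / (n_bg / bg_bases)
        out[label] = SnpEnrichment(
            label, n_in, n_bg, pps_bases, bg_bases, fold, table, chi2, p
        )
    return out


@dataclass
class SynNonsynResult:
    ratio_in_pps: float
    ratio_background: float
    chi_squared: float
    p_value: float
    table: ContingencyTable


def syn_nonsyn_ratio(
    snps: Sequence[SNPRecord], pps_list: Sequence, regions: RegionMap
) -> SynNonsynResult:
    """Synonymous/non-synonymous ratio inside PPSs vs the matched background.

    A stratum without non-synonymous SNPs yields an infinite ratio; the
    chi-squared on the 2x2 class-by-stratum table is still reported.
    """
    pps_merged, background = _matched_background(pps_list, regions)
    classified = [s for s in snps if s.functional_class in ("synonymous", "nonsynonymous")]

    def counts(merged) -> tuple[int, int]:
        inside = _snps_in(classified, merged)
        syn = sum(1 for s in inside if s.functional_class == "synonymous")
        return syn, len(inside) - syn

    syn_in, non_in = counts(pps_merged)
    syn_bg, non_bg = counts(background)
    table = ContingencyTable([[syn_in, non_in], [syn_bg, non_bg]])
    chi2, p = table.chi_squared()
    ratio_in = syn_in / non_in if non_in > 0 else float("inf")
    ratio_bg = syn_bg / non_bg if non_bg > 0 else float("inf")
    return SynNonsynResult(ratio_in, ratio_bg, chi2, p, table)
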