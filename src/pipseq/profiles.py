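"""Metagene and end-anchored positional PPS density profiles.

A metagene profile rescales every region of one genic class onto a common
[0, 1) axis of ``n_bins`` bins and accumulates PPS-covered bases into them,
oriented 5'->3' by strand.  End-anchored profiles count per-nucleotide PPS
coverage frequency at fixed offsets from each region's 5' and 3' ends.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .caller import PPS
from .model import GenomicInterval, Strand, merged_by_key, overlap_with_merged


@dataclass
class Profile:
    """Positional density with the number of regions that contributed."""

    positions: np.ndarray  # axis labels (bin index or signed nt offset)
    density: np.ndarray
    n_regions: int
    raw_mass: np.ndarray | None = None  # unnormalized covered-base mass per bin


def _pps_intervals(pps: Sequence) -> list[GenomicInterval]:
    return [p.interval if isinstance(p, PPS) else p for p in pps]


def _covered_rel(
    merged: list[tuple[int, int]], region: GenomicInterval
) -> list[tuple[float, float]]:
    """PPS-covered pieces of the region in strand-oriented relative coords."""
    pieces: list[tuple[float, float]] = []
    for s, e in merged:
        os_, oe = max(s, region.start), min(e, region.end)
        if os_ >= oe:
            continue
        if region.strand is Strand.MINUS:
            pieces.append((region.end - oe, region.end - os_))
        else:
            pieces.append((os_ - region.start, oe - region.start))
    return sorted(pieces)


def metagene_profile(
    pps: Sequence,
    regions: Sequence[GenomicInterval],
    n_bins: int = 100,
    normalize: bool = True,
) -> Profile:
    """Binned PPS base density across regions rescaled to a common axis.

    Regions shorter than ``n_bins`` contribute fractional bin overlaps
    rather than being dropped.  With ``normalize`` the density is divided
    by its own maximum (unit-height curves); the raw per-bin covered-base
    mass is kept alongside either way.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not regions:
        raise ValueError("no regions supplied")
    merged = merged_by_key(_pps_intervals(pps))
    mass = np.zeros(n_bins)
    density = np.zeros(n_bins)
    edges = np.arange(n_bins + 1)
    for region in regions:
        m = merged.get((region.chrom, region.strand), [])
        L = region.length
        scale = n_bins / L  # relative nt -> bin units
        for a, b in _covered_rel(m, region):
            lo, hi = a * scale, b * scale
            frac = np.clip(np.minimum(hi, edges[1:]) - np.maximum(lo, edges[:-1]), 0, None)
            mass += frac / scale  # back to nt so total mass = covered bases
            density += frac  # per-bin occupancy in bin units
    if normalize and density.max() > 0:
        density = density / density.max()
    else:
        density = density / len(regions)
    return Profile(positions=np.arange(n_bins), density=density, n_regions=len(regions), raw_mass=mass)


def end_anchored_profile(
    pps: Sequence,
    regions: Sequence[GenomicInterval],
    flank_nt: int = 50,
    anchors: tuple[str, ...] = ("start", "end"),
) -> Profile:
    """Per-nt PPS coverage frequency near region ends.

    Offsets run 1..flank_nt inward from the 5' end and then flank_nt..1
    inward from the 3' end (strand-oriented), averaged over the regions
    long enough to contribute each offset.  Position labels are positive
    for the 5' half and negative for the 3' half.
    """
    if flank_nt < 1:
        raise ValueError("flank_nt must be >= 1")
    if not regions:
        raise ValueError("no regions supplied")
    merged = merged_by_key(_pps_intervals(pps))
    use_start = "start" in anchors
    use_end = "end" in anchors
    n_half = flank_nt
    cov5 = np.zeros(n_half)
    n5 = np.zeros(n_half)
    cov3 = np.zeros(n_half)
    n3 = np.zeros(n_half)
    for region in regions:
        m = merged.get((region.chrom, region.strand), [])
        L = region.length
        k = min(flank_nt, L)
        # strand-oriented absolute position of relative offset o (0-based)
        def genomic(rel: int) -> int:
            if region.strand is Strand.MINUS:
                return region.end - 1 - rel
            return region.start + rel
        if use_start:
            for o in range(k):
                g = genomic(o)
                cov5[o] += 1 if overlap_with_merged(m, g, g + 1) else 0
                n5[o] += 1
        if use_end:
            for o in range(k):
                g = genomic(L - 1 - o)
                cov3[o] += 1 if overlap_with_merged(m, g, g + 1) else 0
                n3[o] += 1
    halves = []
    positions = []
    if use_start:
        halves.append(np.divide(cov5, n5, out=np.zeros_like(cov5), where=n5 > 0))
        positions.append(np.arange(1, flank_nt + 1))
    if use_end:
        # offsets flank_nt..1 from the 3' end, reading toward it
        halves.append(np.divide(cov3, n3, out=np.zeros_like(cov3), where=n3 > 0)[::-1])
        positions.append(-np.arange(flank_nt, 0, -1))
    return Profile(
        positions=np.concatenate(positions),
        density=np.concatenate(halves),
        n_regions=len(regions),
    )
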