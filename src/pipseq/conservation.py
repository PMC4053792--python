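"""Per-base conservation of PPSs versus equal-sized flanking regions.

Any per-base score track (e.g. SiPhy-pi log-odds read from bedGraph) is
accepted; bases without data stay missing (NaN) and are never imputed.
Each PPS is compared with its immediately adjacent upstream and downstream
flanks of the same length, and significance follows a chi-squared test on
the above/below-pooled-median classification of the per-interval means.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .caller import PPS
from .enrichment import ContingencyTable
from .model import GenomicInterval, Strand


@dataclass
class ScoreTrack:
    """Unstranded per-chromosome float arrays; NaN marks missing bases."""

    data: dict[str, np.ndarray]

    @classmethod
    def from_bedgraph(cls, path, chrom_lengths: dict[str, int] | None = None) -> "ScoreTrack":
        from .io import read_bedgraph

        return cls(data=read_bedgraph(path, chrom_lengths))

    def interval_values(self, iv: GenomicInterval) -> np.ndarray:
        """Clipped per-base values over the interval (may contain NaN)."""
        arr = self.data.get(iv.chrom)
        if arr is None:
            return np.array([])
        return arr[max(0, iv.start) : min(len(arr), iv.end)]

    def interval_mean(self, iv: GenomicInterval) -> float | None:
        vals = self.interval_values(iv)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else None


def interval_mean_scores(track: ScoreTrack, intervals: Sequence[GenomicInterval]) -> list[float | None]:
    """Mean score over the non-missing bases of each interval (None if no data)."""
    return [track.interval_mean(iv) for iv in intervals]


@dataclass
class PpsFlankComparison:
    pps_means: list[float | None]
    upstream_means: list[float | None]
    downstream_means: list[float | None]
    chi_squared: float
    p_value: float
    table: ContingencyTable | None

    def pooled_flank(self) -> np.ndarray:
        vals = [m for m in self.upstream_means + self.downstream_means if m is not None]
        return np.asarray(vals)

    def pps_values(self) -> np.ndarray:
        return np.asarray([m for m in self.pps_means if m is not None])

    def cumulative(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF support/probabilities for plotting or comparison."""
        x = np.sort(values)
        return x, np.arange(1, len(x) + 1) / len(x)


def pps_vs_flank(track: ScoreTrack, pps_list: Sequence) -> PpsFlankComparison:
    """Per-PPS mean scores against equal-sized immediately adjacent flanks.

    Flanks truncated by a chromosome edge (or without any scored base) are
    reported missing.  The chi-squared statistic dichotomizes all interval
    means at the pooled (PPS + flank) median.
    """
    pps_means: list[float | None] = []
    up_means: list[float | None] = []
    down_means: list[float | None] = []
    for p in pps_list:
        iv = p.interval if isinstance(p, PPS) else p
        L = iv.length
        pps_means.append(track.interval_mean(iv))
        if iv.start - L >= 0:
            up_means.append(track.interval_mean(GenomicInterval(iv.chrom, iv.start - L, iv.start)))
        else:
            up_means.append(None)
        arr = track.data.get(iv.chrom)
        if arr is not None and iv.end + L <= len(arr):
            down_means.append(track.interval_mean(GenomicInterval(iv.chrom, iv.end, iv.end + L)))
        else:
            down_means.append(None)

    pps_vals = np.asarray([m for m in pps_means if m is not None])
    flank_vals = np.asarray([m for m in up_means + down_means if m is not None])
    if pps_vals.size == 0 or flank_vals.size == 0:
        return PpsFlankComparison(pps_means, up_means, down_means, 0.0, 1.0, None)
    median = float(np.median(np.concatenate([pps_vals, flank_vals])))
    table = ContingencyTable(
        [
            [int((pps_vals > median).sum()), int((pps_vals <= median).sum())],
            [int((flank_vals > median).sum()), int((flank_vals <= median).sum())],
        ]
    )
    chi2, p = table.chi_squared()
    return PpsFlankComparison(pps_means, up_means, down_means, chi2, p, table)


def rank_sum_pps_vs_flank(track: ScoreTrack, pps_list: Sequence) -> tuple[float, float]:
    """Mann-Whitney alternative to the median-split chi-squared (not default)."""
    cmp = pps_vs_flank(track, pps_list)
    res = stats.mannwhitneyu(cmp.pps_values(), cmp.pooled_flank(), alternative="greater")
    return float(res.statistic), float(res.pvalue)


def positional_profile(
    track: ScoreTrack,
    pps_list: Sequence,
    edge_nt: int = 25,
    flank_nt: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean conservation across {upstream flank, first/last edge_nt of the
    PPS, downstream flank}, strand-oriented.

    Returns (positions, means); the axis has 2*flank_nt + 2*edge_nt
    positions ordered 5'->3'.  PPSs shorter than 2*edge_nt contribute only
    their clipped interior positions; missing bases are excluded per
    position.  Stratification by region class is done by the caller
    passing a class-filtered PPS subset.
    """
    n_pos = 2 * flank_nt + 2 * edge_nt
    total = np.zeros(n_pos)
    count = np.zeros(n_pos)
    for p in pps_list:
        iv = p.interval if isinstance(p, PPS) else p
        L = iv.length
        minus = iv.strand is Strand.MINUS

        def value_at(g: int) -> float:
            arr = track.data.get(iv.chrom)
            if arr is None or not (0 <= g < len(arr)):
                return np.nan
            return arr[g]

        def oriented(rel: int) -> int:
            # rel counted 5'->3' from the PPS 5' end; negatives reach upstream
            return (iv.end - 1 - rel) if minus else (iv.start + rel)

        for j in range(n_pos):
            if j < flank_nt:  # upstream flank
                rel = j - flank_nt
            elif j < flank_nt + edge_nt:  # first edge_nt inside
                rel = j - flank_nt
                if rel >= L:
                    continue
            elif j < flank_nt + 2 * edge_nt:  # last edge_nt inside
                rel = L - (flank_nt + 2 * edge_nt - j)
                if rel < 0:
                    continue
            else:  # downstream flank
                rel = L + (j - flank_nt - 2 * edge_nt)
            v = value_at(oriented(rel))
            if np.isfinite(v):
                total[j] += v
                count[j] += 1
    means = np.divide(total, count, out=np.full(n_pos, np.nan), where=count > 0)
    positions = np.arange(n_pos)
    return positions, means
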