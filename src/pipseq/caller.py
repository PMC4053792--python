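"""Protein-protected site (PPS) calling.

Per base, the footprint library's read depth f_i is scored against the
digestion control's depth c_i under a Poisson model: with depth-ratio
normalization r = N_footprint / N_control, the null rate is
lambda_i = r * max(c_i, lambda_min) and the enrichment score is

    s_i = -log10 P(X >= f_i),   X ~ Poisson(lambda_i),

zero wherever f_i = 0 and capped at 350.  Candidate regions are maximal
runs of bases with s_i above a threshold (gap-merged, length-filtered), and
the working threshold is set by a permutation FDR: reads from both
libraries are pooled and randomly relabeled (library sizes preserved), the
score profile and region counts are recomputed, and the estimated FDR at a
threshold t is the mean null region count at t over the observed count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

from .coverage import CoverageTrack, Library, compute_coverage, subsample_alignments
from .model import GenomicInterval, Strand
from .segmentation import segment_above_threshold

SCORE_CAP = 350.0
_LN10 = np.log(10.0)


@dataclass
class CallerConfig:
    """Knobs of the PPS caller.

    fdr_target     target false discovery rate for the working threshold
    lambda_min     pseudo-rate floor (control reads) so zero-control bases
                   cannot produce infinite scores
    min_length     minimum region length in nt
    max_gap        sub-threshold gap (nt) across which regions are merged
    n_permutations read-label permutations for the FDR null
    seed           RNG seed for permutations and subsampling
    n_grid_max     at most this many score thresholds on the FDR grid
    """

    fdr_target: float = 0.05
    lambda_min: float = 0.5
    min_length: int = 15
    max_gap: int = 0
    n_permutations: int = 10
    seed: int = 0
    n_grid_max: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.fdr_target < 1):
            raise ValueError("fdr_target must be in (0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ScoreProfile:
    """Per-(chrom, strand) arrays of per-base enrichment scores."""

    data: dict[tuple[str, Strand], np.ndarray]

    def array(self, chrom: str, strand: Strand) -> np.ndarray:
        return self.data.get((chrom, strand), np.zeros(0))


@dataclass(frozen=True)
class PPS:
    """A called protein-protected site."""

    interval: GenomicInterval
    score: float
    mean_score: float
    footprint_reads: int
    control_reads: int
    fdr_threshold_used: float

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class FDRRow:
    score_threshold: float
    observed_region_count: int
    mean_null_region_count: float
    estimated_fdr: float


@dataclass
class FDRTable:
    """Permutation FDR estimates over a grid of score thresholds.

    ``estimated_fdr`` is monotonized (running max from the highest threshold
    down), so it is non-increasing as the threshold increases.
    """

    rows: list[FDRRow] = field(default_factory=list)

    def working_threshold(self, fdr_target: float) -> float | None:
        """Smallest grid threshold whose estimated FDR is <= the target."""
        for row in self.rows:  # rows sorted by ascending threshold
            if row.estimated_fdr <= fdr_target:
                return row.score_threshold
        return None


def poisson_enrichment_score(f, lam) -> np.ndarray:
    """-log10 upper-tail Poisson probability P(X >= f), elementwise.

    Accurate across the whole range: near-1 tails go through log1p of the
    complementary CDF, tails below double underflow through a log-space
    series, everything capped at SCORE_CAP.  f must be >= 1.
    """
    f = np.asarray(f, dtype=float)
    lam = np.asarray(lam, dtype=float)
    f, lam = np.broadcast_arrays(f, lam)
    # P(X >= f) = gammainc(f, lam) (regularized lower); P(X <= f-1) = gammaincc
    tail = special.gammainc(f, lam)
    s = np.empty(f.shape)

    big = tail >= 0.5
    if big.any():
        q = special.gammaincc(f[big], lam[big])
        s[big] = -np.log1p(-q) / _LN10
    mid = (~big) & (tail > 1e-280)
    s[mid] = -np.log10(tail[mid])
    tiny = (~big) & ~mid
    if tiny.any():
        s[tiny] = _log_tail_series(f[tiny], lam[tiny])
    return np.minimum(s, SCORE_CAP)


def _log_tail_series(f: np.ndarray, lam: np.ndarray, n_terms: int = 500) -> np.ndarray:
    """-log10 tail by logsumexp over the first n_terms tail terms.

    Only reached when the tail is < 1e-280, i.e. f >> lam, where successive
    terms shrink geometrically and 500 terms are far beyond convergence.
    """
    k = f[:, None] + np.arange(n_terms)[None, :]
    logterms = k * np.log(lam[:, None]) - lam[:, None] - special.gammaln(k + 1)
    return -special.logsumexp(logterms, axis=1) / _LN10


def enrichment_score_profile(
    fp: CoverageTrack, ctl: CoverageTrack, cfg: CallerConfig
) -> ScoreProfile:
    """Per-base footprint-vs-control enrichment scores."""
    if fp.library_size <= 0 or ctl.library_size <= 0:
        raise ValueError("both libraries must be non-empty to form the depth ratio")
    if set(fp.data) != set(ctl.data):
        raise ValueError("footprint and control tracks cover different (chrom, strand) sets")
    r = fp.library_size / ctl.library_size
    out: dict[tuple[str, Strand], np.ndarray] = {}
    for key, f_arr in fp.data.items():
        c_arr = ctl.data[key]
        if len(f_arr) != len(c_arr):
            raise ValueError(f"track length mismatch on {key}")
        s = np.zeros(len(f_arr))
        nz = f_arr > 0
        if nz.any():
            lam = r * np.maximum(c_arr[nz], cfg.lambda_min)
            s[nz] = poisson_enrichment_score(f_arr[nz], lam)
        out[key] = s
    return ScoreProfile(data=out)


def _count_reads(track: CoverageTrack, key, start: int, end: int) -> int:
    spans = getattr(track, "_spans", None)
    if spans is None or key not in spans:
        return 0
    starts_sorted, ends_sorted = spans[key]
    return int(
        np.searchsorted(starts_sorted, end, side="left")
        - np.searchsorted(ends_sorted, start, side="right")
    )


def _attach_spans(track: CoverageTrack, lib: Library) -> None:
    """Cache sorted read-span arrays on a track for fast overlap counting."""
    spans: dict = {}
    for r in lib.reads:
        key = (r.chrom, r.strand)
        spans.setdefault(key, ([], []))
        spans[key][0].append(r.span[0])
        spans[key][1].append(r.span[1])
    track._spans = {  # type: ignore[attr-defined]
        k: (np.sort(np.asarray(v[0])), np.sort(np.asarray(v[1]))) for k, v in spans.items()
    }


def segment_regions(
    sp: ScoreProfile,
    threshold: float,
    cfg: CallerConfig,
    fp_track: CoverageTrack | None = None,
    ctl_track: CoverageTrack | None = None,
    fdr_threshold_used: float = float("nan"),
) -> list[PPS]:
    """Maximal above-threshold runs as candidate PPSs.

    Runs separated by <= max_gap bases are merged and merged runs shorter
    than min_length discarded.  Read counts are taken from the tracks'
    cached read spans when available.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out: list[PPS] = []
    for key in sorted(sp.data, key=lambda k: (k[0], k[1].value)):
        arr = sp.data[key]
        for s, e in segment_above_threshold(arr, threshold, cfg.max_gap, cfg.min_length):
            chrom, strand = key
            out.append(
                PPS(
                    interval=GenomicInterval(chrom, s, e, strand),
                    score=float(arr[s:e].max()),
                    mean_score=float(arr[s:e].mean()),
                    footprint_reads=_count_reads(fp_track, key, s, e) if fp_track else 0,
                    control_reads=_count_reads(ctl_track, key, s, e) if ctl_track else 0,
                    fdr_threshold_used=fdr_threshold_used,
                )
            )
    return out


def _shared_chrom_lengths(fp: Library, ctl: Library) -> dict[str, int]:
    lengths = fp.chrom_lengths()
    for chrom, ln in ctl.chrom_lengths().items():
        lengths[chrom] = max(lengths.get(chrom, 0), ln)
    return lengths


def _candidate_region_scores(sp: ScoreProfile, cfg: CallerConfig) -> np.ndarray:
    """Sorted max scores of candidate regions segmented at the smallest
    positive score (i.e. over all scored territory)."""
    scores: list[float] = []
    for arr in sp.data.values():
        pos = arr[arr > 0]
        if pos.size == 0:
            continue
        tmin = float(pos.min())
        for s, e in segment_above_threshold(arr, tmin, cfg.max_gap, cfg.min_length):
            scores.append(float(arr[s:e].max()))
    return np.sort(scores)


def _counts_at(sorted_scores: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Number of region scores >= each grid threshold."""
    return sorted_scores.size - np.searchsorted(sorted_scores, grid, side="left")


def _null_counts(
    fp: Library,
    ctl: Library,
    grid: np.ndarray,
    cfg: CallerConfig,
    chrom_lengths: dict[str, int],
) -> np.ndarray:
    """Mean region count per grid threshold under read-label permutation."""
    pooled = fp.reads + ctl.reads
    n_fp = len(fp.reads)
    rng = np.random.default_rng(cfg.seed)
    counts = np.zeros((cfg.n_permutations, grid.size))
    for p in range(cfg.n_permutations):
        order = rng.permutation(len(pooled))
        fp_null = Library("null_fp", "footprint", [pooled[i] for i in order[:n_fp]])
        ctl_null = Library("null_ctl", "control", [pooled[i] for i in order[n_fp:]])
        sp_null = enrichment_score_profile(
            compute_coverage(fp_null, chrom_lengths),
            compute_coverage(ctl_null, chrom_lengths),
            cfg,
        )
        counts[p] = _counts_at(_candidate_region_scores(sp_null, cfg), grid)
    return counts.mean(axis=0)


def _build_fdr_table(
    grid: np.ndarray, observed: np.ndarray, null_mean: np.ndarray
) -> FDRTable:
    raw = null_mean / np.maximum(1, observed)
    mono = np.maximum.accumulate(raw[::-1])[::-1]
    rows = [
        FDRRow(float(t), int(o), float(nm), float(fdr))
        for t, o, nm, fdr in zip(grid, observed, null_mean, mono)
    ]
    return FDRTable(rows=rows)


def permutation_fdr(fp: Library, ctl: Library, cfg: CallerConfig) -> FDRTable:
    """Estimate the FDR over the observed score-threshold grid by read-label
    permutation (library sizes preserved, seeded)."""
    table, _, _, _ = _fdr_with_profile(fp, ctl, cfg)
    return table


def _fdr_with_profile(fp: Library, ctl: Library, cfg: CallerConfig):
    chrom_lengths = _shared_chrom_lengths(fp, ctl)
    fp_track = compute_coverage(fp, chrom_lengths)
    ctl_track = compute_coverage(ctl, chrom_lengths)
    _attach_spans(fp_track, fp)
    _attach_spans(ctl_track, ctl)
    sp = enrichment_score_profile(fp_track, ctl_track, cfg)
    observed_scores = _candidate_region_scores(sp, cfg)
    grid = np.unique(observed_scores)
    if grid.size > cfg.n_grid_max:
        # keep full resolution in the upper tail, thin the rest by quantiles
        n_top = cfg.n_grid_max // 2
        qs = np.quantile(grid[:-n_top], np.linspace(0, 1, cfg.n_grid_max - n_top), method="nearest")
        grid = np.unique(np.concatenate([qs, grid[-n_top:]]))
    if grid.size == 0:
        return FDRTable(rows=[]), sp, fp_track, ctl_track
    observed = _counts_at(observed_scores, grid)
    null_mean = _null_counts(fp, ctl, grid, cfg, chrom_lengths)
    return _build_fdr_table(grid, observed, null_mean), sp, fp_track, ctl_track


def call_pps(fp: Library, ctl: Library, cfg: CallerConfig) -> tuple[list[PPS], FDRTable]:
    """Call PPSs at the smallest score threshold meeting the FDR target.

    Thresholding is at the region level: candidate regions are segmented
    once over all scored territory (so each keeps its full extent) and a
    candidate is called when its region score — the max per-base score —
    reaches the working threshold, ties included.  Returns an empty call
    list (with the FDR table) when no threshold qualifies or the footprint
    library is empty.
    """
    if fp.size == 0:
        return [], FDRTable(rows=[])
    table, sp, fp_track, ctl_track = _fdr_with_profile(fp, ctl, cfg)
    threshold = table.working_threshold(cfg.fdr_target)
    if threshold is None:
        return [], table
    calls: list[PPS] = []
    for key in sorted(sp.data, key=lambda k: (k[0], k[1].value)):
        arr = sp.data[key]
        pos = arr[arr > 0]
        if pos.size == 0:
            continue
        tmin = float(pos.min())
        for s, e in segment_above_threshold(arr, tmin, cfg.max_gap, cfg.min_length):
            score = float(arr[s:e].max())
            if score < threshold:
                continue
            chrom, strand = key
            calls.append(
                PPS(
                    interval=GenomicInterval(chrom, s, e, strand),
                    score=score,
                    mean_score=float(arr[s:e].mean()),
                    footprint_reads=_count_reads(fp_track, key, s, e),
                    control_reads=_count_reads(ctl_track, key, s, e),
                    fdr_threshold_used=threshold,
                )
            )
    return calls, table


def saturation_curve(
    fp: Library, ctl: Library, fractions: Sequence[float], cfg: CallerConfig
) -> list[tuple[float, int]]:
    """PPS yield as a function of read depth.

    Both libraries are subsampled at the same fraction (independent seeds
    derived from cfg.seed) and the caller re-run at each point.
    """
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError("fractions must lie in (0, 1]")
    seed_rng = np.random.default_rng(cfg.seed)
    out: list[tuple[float, int]] = []
    for frac in fractions:
        s1, s2 = (int(x) for x in seed_rng.integers(0, 2**31 - 1, size=2))
        fp_sub = fp if frac == 1.0 else subsample_alignments(fp, frac, s1)
        ctl_sub = ctl if frac == 1.0 else subsample_alignments(ctl, frac, s2)
        calls, _ = call_pps(fp_sub, ctl_sub, cfg)
        out.append((float(frac), len(calls)))
    return out
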