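"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately written with a different algorithm (and,
for the Poisson tail, different arithmetic) from the package code paths it
validates.
"""
from __future__ import annotations

import mpmath as mp

mp.mp.dps = 40


def poisson_tail_neglog10(f: int, lam) -> mp.mpf:
    """-log10 P(X >= f) by arbitrary-precision term-by-term summation."""
    if f == 0:
        return mp.mpf(0)
    lam = mp.mpf(lam)
    term = mp.e ** (-lam) * lam**f / mp.factorial(f)
    total = mp.mpf(0)
    k = f
    while True:
        total += term
        k += 1
        term = term * lam / k
        if k > f + 10 and term < total * mp.mpf("1e-50"):
            break
    return -mp.log10(total)


def brute_segments(values, threshold, max_gap, min_run):
    """Maximal qualifying runs by a plain left-to-right scan with explicit
    gap bridging (no vectorization)."""
    qual = [v >= threshold for v in values]
    runs = []
    start = None
    for i, q in enumerate(qual):
        if q and start is None:
            start = i
        elif not q and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(qual)))
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [r for r in merged if r[1] - r[0] >= min_run]


def chi2_closed_form(a, b, c, d):
    """n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for a 2x2 table."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def brute_annotate(pps_intervals, labeled_regions):
    """All-pairs overlap scan: for each PPS, the set of (class, tx) labels
    whose interval overlaps it by >= 1 base on the same strand."""
    out = []
    for iv in pps_intervals:
        labels = set()
        for tx, region, cls in labeled_regions:
            if (
                region.chrom == iv.chrom
                and region.strand is iv.strand
                and region.start < iv.end
                and iv.start < region.end
            ):
                labels.add((cls, tx))
        out.append(labels)
    return out


def brute_window_sums(arr, window, step):
    out = []
    for start in range(0, len(arr), step):
        end = min(start + window, len(arr))
        out.append(sum(arr[start:end]))
    return out


def brute_metagene_mass(covered_rel_pairs, length, n_bins):
    """Per-bin covered-base mass by per-base accumulation at fine resolution."""
    mass = [0.0] * n_bins
    for a, b in covered_rel_pairs:
        pos = float(a)
        while pos < b:
            bin_idx = min(n_bins - 1, int(pos * n_bins / length))
            bin_end = (bin_idx + 1) * length / n_bins
            stop = min(float(b), bin_end)
            if stop <= pos:  # float-boundary guard
                stop = min(float(b), pos + 1e-9)
            mass[bin_idx] += stop - pos
            pos = stop
    return mass
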