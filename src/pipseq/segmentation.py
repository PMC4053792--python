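"""Run/gap/min-run segmentation shared by the PPS caller and the
transcribed-region segmenter.

The rule: take maximal runs of qualifying bases, merge runs separated by at
most ``max_gap`` non-qualifying bases, then drop merged runs shorter than
``min_run``.
"""
from __future__ import annotations

import numpy as np


def segment_mask(mask: np.ndarray, max_gap: int = 0, min_run: int = 1) -> list[tuple[int, int]]:
    """Segment a boolean per-base mask into merged, length-filtered runs."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    # boundaries of maximal runs of True
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    merged: list[tuple[int, int]] = [(int(starts[0]), int(ends[0]))]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], int(e))
        else:
            merged.append((int(s), int(e)))
    return [(s, e) for s, e in merged if e - s >= min_run]


def segment_above_threshold(
    values: np.ndarray, threshold: float, max_gap: int = 0, min_run: int = 1
) -> list[tuple[int, int]]:
    """Segment maximal runs with ``values >= threshold``."""
    return segment_mask(np.asarray(values) >= threshold, max_gap=max_gap, min_run=min_run)
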