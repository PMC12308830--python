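"""Half-open interval arithmetic on numpy arrays.

All coordinates are 0-based half-open. These helpers back the density,
masking and telomere-profile computations; they are deliberately small and
fully vectorised so that window statistics over millions of annotations stay
cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_intervals",
    "coverage_before",
    "window_coverage",
    "points_in_intervals",
    "intersect_lengths",
]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals, returned sorted and disjoint.

    Touching intervals ([0,5) and [5,9)) are merged.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    if np.any(ends < starts):
        raise ValueError("interval end < start")
    order = np.argsort(starts, kind="mergesort")
    s = starts[order]
    e = ends[order]
    cummax = np.maximum.accumulate(e)
    new_run = np.ones(s.size, dtype=bool)
    new_run[1:] = s[1:] > cummax[:-1]
    run_starts = np.flatnonzero(new_run)
    ms = s[new_run]
    me = np.maximum.reduceat(e, run_starts)
    return ms, me


def coverage_before(x: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Covered bases in [0, x) given *merged* intervals (sorted, disjoint)."""
    x = np.asarray(x, dtype=np.int64)
    if starts.size == 0:
        return np.zeros(x.shape, dtype=np.int64)
    lengths = ends - starts
    cum = np.concatenate([[0], np.cumsum(lengths)])
    i = np.searchsorted(starts, x, side="right")
    total = cum[i]
    # the last interval starting before x may extend past it
    j = i - 1
    valid = j >= 0
    overshoot = np.zeros(x.shape, dtype=np.int64)
    overshoot[valid] = np.clip(ends[j[valid]] - x[valid], 0, lengths[j[valid]])
    return total - overshoot


def window_coverage(
    win_starts: np.ndarray,
    win_ends: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """Bases of each window covered by the union of (merged) intervals."""
    return coverage_before(win_ends, starts, ends) - coverage_before(win_starts, starts, ends)


def points_in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside the merged intervals."""
    pos = np.asarray(pos, dtype=np.int64)
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    i = np.searchsorted(starts, pos, side="right") - 1
    inside = i >= 0
    inside[inside] = pos[inside] < ends[i[inside]]
    return inside


def intersect_lengths(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> int:
    """Total overlap between two merged interval sets."""
    a_starts, a_ends = merge_intervals(a_starts, a_ends)
    if a_starts.size == 0 or np.asarray(b_starts).size == 0:
        return 0
    cov = window_coverage(np.asarray(b_starts), np.asarray(b_ends), a_starts, a_ends)
    return int(cov.sum())
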