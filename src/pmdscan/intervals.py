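"""Half-open interval arithmetic on sorted per-chromosome arrays.

Internal helpers shared by the comparison, annotation and post-processing
modules. All intervals are 0-based half-open [start, end). Functions take
parallel numpy arrays of starts and ends that are sorted by start; callers
that cannot guarantee merged (non-overlapping) input should pass through
:func:`merge` first.
"""
from __future__ import annotations

import numpy as np


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or abutting intervals. Input must be sorted by start."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:].tolist(), ends[1:].tolist()):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def total_length(starts: np.ndarray, ends: np.ndarray) -> int:
    return int(np.sum(np.asarray(ends, dtype=np.int64) - np.asarray(starts, dtype=np.int64)))


def intersect_length(
    s1: np.ndarray, e1: np.ndarray, s2: np.ndarray, e2: np.ndarray
) -> int:
    """Total basepairs shared by two merged, sorted interval lists."""
    i = j = 0
    total = 0
    n1, n2 = len(s1), len(s2)
    while i < n1 and j < n2:
        lo = max(s1[i], s2[j])
        hi = min(e1[i], e2[j])
        if hi > lo:
            total += hi - lo
        if e1[i] <= e2[j]:
            i += 1
        else:
            j += 1
    return int(total)


def overlap_with(
    qstart: int, qend: int, starts: np.ndarray, ends: np.ndarray
) -> int:
    """Basepairs of [qstart, qend) covered by a merged, sorted interval list."""
    if qend <= qstart or len(starts) == 0:
        return 0
    lo = int(np.searchsorted(ends, qstart, side="right"))
    hi = int(np.searchsorted(starts, qend, side="left"))
    total = 0
    for k in range(lo, hi):
        total += max(0, min(qend, int(ends[k])) - max(qstart, int(starts[k])))
    return total


def points_in(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: which points fall inside a merged, sorted interval list."""
    points = np.asarray(points, dtype=np.int64)
    if len(starts) == 0:
        return np.zeros(points.shape, dtype=bool)
    idx = np.searchsorted(starts, points, side="right") - 1
    inside = idx >= 0
    inside[inside] &= points[inside] < ends[idx[inside]]
    return inside
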