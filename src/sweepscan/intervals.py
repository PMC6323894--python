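"""Small utilities on 0-based half-open genomic intervals.

Intervals are ``(k, 2)`` integer arrays sorted by start.  These are the only
interval operations the pipeline needs (union length, overlap, containment,
distance); each is a few lines on sorted arrays.
"""

from __future__ import annotations

import numpy as np


def as_intervals(ivs) -> np.ndarray:
    arr = np.asarray(ivs, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be a (k, 2) array")
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("intervals must satisfy start < end")
    return arr[np.argsort(arr[:, 0], kind="stable")]


def union(ivs) -> np.ndarray:
    """Merge overlapping or book-ended intervals into a disjoint union."""
    arr = as_intervals(ivs)
    if len(arr) == 0:
        return arr
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def intersect_length(start: int, end: int, ivs) -> int:
    """Total bases of ``[start, end)`` covered by the union of ``ivs``."""
    total = 0
    for s, e in union(ivs):
        total += max(0, min(end, e) - max(start, s))
    return int(total)


def overlaps_any(start: int, end: int, ivs) -> bool:
    arr = as_intervals(ivs)
    return any(min(end, e) - max(start, s) > 0 for s, e in arr)


def contained_in_union(start: int, end: int, ivs) -> bool:
    """True iff ``[start, end)`` lies entirely inside the union of ``ivs``."""
    return intersect_length(start, end, ivs) == end - start


def distance_bp(start: int, end: int, ivs) -> int | None:
    """bp separation to the closest interval (0 if overlapping); None if empty."""
    arr = as_intervals(ivs)
    if len(arr) == 0:
        return None
    best = None
    for s, e in arr:
        if min(end, e) - max(start, s) > 0:
            return 0
        d = s - end if s >= end else start - e
        best = d if best is None else min(best, d)
    return int(best)
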