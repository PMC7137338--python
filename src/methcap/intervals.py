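"""Half-open interval algebra on integer genomic coordinates.

All coordinates are 0-based, half-open ``[start, end)``, matching BED
conventions. Interval lists are ``(n, 2)`` integer arrays per chromosome.
"""

from __future__ import annotations

import numpy as np


def as_interval_array(intervals) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to a sorted (n, 2) int array."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if arr.size and np.any(arr[:, 1] < arr[:, 0]):
        bad = arr[arr[:, 1] < arr[:, 0]][0]
        raise ValueError(f"interval end < start: {tuple(bad)}")
    if arr.size:
        arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    return arr


def merge_intervals(intervals, gap: int = 0) -> np.ndarray:
    """Union of intervals, joining any pair separated by <= ``gap`` bases.

    ``gap=0`` merges only touching/overlapping intervals.
    """
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s - cur_e <= gap:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


def subtract_intervals(a, b) -> np.ndarray:
    """Set difference a \\ b. Both inputs may be unsorted; result is merged."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intersect_length(query_start: int, query_end: int, intervals) -> int:
    """Overlap length (bp) between one query and the union of a set of
    intervals (duplicates and internal overlaps do not double-count)."""
    arr = merge_intervals(intervals)
    if len(arr) == 0:
        return 0
    lo = np.minimum(np.maximum(arr[:, 0], query_start), query_end)
    hi = np.maximum(np.minimum(arr[:, 1], query_end), query_start)
    return int(np.maximum(hi - lo, 0).sum())


def overlaps_any(query_start: int, query_end: int, intervals) -> bool:
    """True iff the query shares >= 1 bp with any interval in the set."""
    arr = as_interval_array(intervals)
    if len(arr) == 0 or query_end <= query_start:
        return False
    # sorted by start: candidate = last interval starting before query end
    idx = np.searchsorted(arr[:, 0], query_end, side="left")
    return bool(np.any(arr[:idx, 1] > query_start))


def clip_intervals(intervals, lo: int, hi: int) -> np.ndarray:
    """Clip all intervals to [lo, hi), dropping any that become empty."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr.copy()
    arr[:, 0] = np.maximum(arr[:, 0], lo)
    arr[:, 1] = np.minimum(arr[:, 1], hi)
    return arr[arr[:, 1] > arr[:, 0]]


def total_length(intervals) -> int:
    arr = merge_intervals(intervals)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())
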