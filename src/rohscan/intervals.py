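"""Interval arithmetic on 1-based, inclusive genomic intervals.

All interval sets in the package are ``(n, 2)`` integer arrays of
``[start, end]`` rows with ``start <= end``, both inclusive, 1-based.
The length of an interval is ``end - start + 1``.  BED conversion
(0-based, half-open) happens only at the I/O boundary (:mod:`rohscan.io`).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge",
    "total_bp",
    "intersect",
    "subtract",
    "clip",
    "coverage_histogram",
]


def as_intervals(pairs) -> np.ndarray:
    """Coerce a sequence of (start, end) pairs to a validated interval array."""
    arr = np.asarray(pairs, dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (n, 2) interval array, got shape {arr.shape}")
    if np.any(arr[:, 0] < 1):
        raise ValueError("interval starts must be >= 1 (1-based coordinates)")
    if np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("interval end < start")
    return arr


def merge(iv: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or bookended (adjacent) intervals."""
    iv = as_intervals(iv)
    if len(iv) == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1] + 1:  # overlap or adjacency merges
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e], dtype=np.int64))
    return np.array(out, dtype=np.int64)


def total_bp(iv: np.ndarray) -> int:
    """Total base pairs covered; input must be non-overlapping (merge first)."""
    iv = as_intervals(iv)
    if len(iv) == 0:
        return 0
    return int(np.sum(iv[:, 1] - iv[:, 0] + 1))


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged interval sets (two-pointer sweep)."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s <= e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(out, dtype=np.int64)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Base pairs of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] < cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] <= e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0] - 1))
            cur = max(cur, b[k, 1] + 1)
            if cur > e:
                break
            k += 1
        if cur <= e:
            out.append((cur, e))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(out, dtype=np.int64)


def clip(iv: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Restrict intervals to [lo, hi], dropping those that fall outside."""
    iv = as_intervals(iv)
    if len(iv) == 0:
        return iv
    s = np.maximum(iv[:, 0], lo)
    e = np.minimum(iv[:, 1], hi)
    keep = s <= e
    return np.column_stack([s[keep], e[keep]])


def coverage_histogram(interval_sets: list[np.ndarray]) -> dict[int, int]:
    """Base pairs covered by exactly k of the given interval sets, for k >= 1.

    Event-point sweep over interval boundaries: +1 at each start, -1 just
    past each end.  Runs in O(m log m) for m intervals total, independent
    of genome length.
    """
    starts = []
    ends = []
    for iv in interval_sets:
        iv = merge(iv)
        if len(iv):
            starts.append(iv[:, 0])
            ends.append(iv[:, 1] + 1)
    if not starts:
        return {}
    events = np.concatenate(
        [
            np.column_stack([np.concatenate(starts), np.ones(sum(map(len, starts)), dtype=np.int64)]),
            np.column_stack([np.concatenate(ends), -np.ones(sum(map(len, ends)), dtype=np.int64)]),
        ]
    )
    pos = events[:, 0]
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], events[order, 1]
    # collapse equal positions
    uniq, idx = np.unique(pos, return_index=True)
    depth_delta = np.add.reduceat(delta, idx)
    depth = np.cumsum(depth_delta)
    span = np.diff(uniq)
    hist: dict[int, int] = {}
    for d, w in zip(depth[:-1], span):
        if d > 0:
            hist[int(d)] = hist.get(int(d), 0) + int(w)
    return hist
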