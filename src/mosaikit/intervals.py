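"""Interval arithmetic on 0-based half-open coordinates.

All genomic intervals inside the package are represented as integer numpy
arrays of shape ``(n, 2)`` with columns ``start, end`` (0-based, half-open),
sorted and disjoint per chromosome.  Conversion from 1-based formats happens
at the I/O boundary only.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge_intervals",
    "total_length",
    "intersect_intervals",
    "positions_in_intervals",
    "coverage_in_windows",
    "tile_windows",
    "pairwise_overlap",
]


def as_intervals(iv) -> np.ndarray:
    """Coerce to an ``(n, 2)`` int64 array; validates start < end."""
    arr = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if arr.size and np.any(arr[:, 1] <= arr[:, 0]):
        bad = arr[arr[:, 1] <= arr[:, 0]][0]
        raise ValueError(f"empty or inverted interval [{bad[0]}, {bad[1]})")
    return arr


def merge_intervals(iv) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals."""
    arr = as_intervals(iv)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_length(iv) -> int:
    arr = as_intervals(iv)
    return int((arr[:, 1] - arr[:, 0]).sum()) if len(arr) else 0


def intersect_intervals(a, b) -> np.ndarray:
    """Intersection of two sorted-disjoint interval sets."""
    a = as_intervals(a)
    b = as_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def positions_in_intervals(pos, iv) -> np.ndarray:
    """Boolean mask: which positions fall inside the interval set."""
    pos = np.asarray(pos, dtype=np.int64)
    arr = as_intervals(iv)
    if len(arr) == 0:
        return np.zeros(len(pos), dtype=bool)
    # flatten boundaries; a position is inside iff searchsorted index is odd
    bounds = arr.ravel()
    idx = np.searchsorted(bounds, pos, side="right")
    return idx % 2 == 1


def _cum_coverage_at(points, iv) -> np.ndarray:
    """Covered bases in [0, x) for each x in ``points`` (vectorized)."""
    arr = as_intervals(iv)
    points = np.asarray(points, dtype=np.int64)
    if len(arr) == 0:
        return np.zeros(len(points), dtype=np.int64)
    starts, ends = arr[:, 0], arr[:, 1]
    cumlen = np.concatenate([[0], np.cumsum(ends - starts)])
    i = np.searchsorted(starts, points, side="right")  # intervals with start < x
    j = np.maximum(i - 1, 0)
    base = np.where(i > 0, cumlen[j], 0)
    partial = np.where(i > 0, np.clip(points - starts[j], 0, (ends - starts)[j]), 0)
    return base + partial


def coverage_in_windows(iv, chrom_length: int, window_size: int) -> np.ndarray:
    """Number of covered (e.g. alignable) bases per tiling window."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    edges = np.arange(0, chrom_length + window_size, window_size)
    edges[-1] = chrom_length
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    cum = _cum_coverage_at(edges, iv)
    return np.diff(cum)


def tile_windows(chrom_length: int, window_size: int) -> np.ndarray:
    """Non-overlapping tiles covering [0, chrom_length); last may be short."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    starts = np.arange(0, chrom_length, window_size, dtype=np.int64)
    ends = np.minimum(starts + window_size, chrom_length)
    return np.stack([starts, ends], axis=1)


def pairwise_overlap(a_start, a_end, b_start, b_end) -> int:
    """Overlap length of two single intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))
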