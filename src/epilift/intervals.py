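"""Small interval-arithmetic helpers shared across modules.

Intervals are 0-based half-open ``(start, end)`` tuples, grouped per
chromosome where needed.  These helpers operate on plain python lists and
are the single place merge/subtract/intersection semantics are defined; the
engine and guideline use :mod:`intervaltree` for stabbing queries on top of
them.
"""

from __future__ import annotations

from typing import Iterable, Sequence

__all__ = [
    "merge_intervals",
    "total_length",
    "subtract_intervals",
    "intersect_length",
    "overlaps_any",
]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge touching/overlapping intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def subtract_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a \\ b on merged interval lists."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_length(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> int:
    """Total overlap length between two interval sets (merged internally)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def overlaps_any(
    interval: tuple[int, int], track: Sequence[tuple[int, int]]
) -> bool:
    """True if ``interval`` overlaps any interval of a merged, sorted track
    by at least 1 bp."""
    import bisect

    s, e = interval
    idx = bisect.bisect_right([t[0] for t in track], s)
    for k in (idx - 1, idx):
        if 0 <= k < len(track):
            ts, te = track[k]
            if ts < e and s < te:
                return True
    return False
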