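"""Closed-interval utilities shared across modules.

All genomic intervals are handled 1-based inclusive in memory (FlyBase
convention); conversion to 0-based half-open happens only at the BED
boundary in :mod:`lethalmap.io`. Two intervals overlap iff they share at
least one base, so abutting intervals ([1, 10] and [11, 20]) do not overlap.
"""

from __future__ import annotations

__all__ = [
    "merge_intervals",
    "union_length",
    "overlap_length",
]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse a list of closed intervals into disjoint sorted intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1] + 1 and end > merged[-1][1]:
            merged[-1][1] = end
        elif start > merged[-1][1] + 1:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total number of bases covered by the union of closed intervals."""
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of shared bases between two closed intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
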