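"""Closed-interval arithmetic on 1-based genomic coordinates.

Every function here works on ``(start, end)`` pairs that are 1-based and
closed (both endpoints included), the convention used throughout the
package. BED input is converted at the I/O boundary.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from intervaltree import IntervalTree


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of closed intervals; overlapping or book-ended runs are merged."""
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"invalid interval ({s}, {e}): start > end")
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_length(ivs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in merge_intervals(ivs))


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of shared bases between two closed intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def gap_between(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Bases strictly between two closed intervals; 0 if they touch or overlap."""
    if overlap_length(a, b) > 0:
        return 0
    return max(a[0], b[0]) - min(a[1], b[1]) - 1


class IntervalIndex:
    """Per-chromosome interval lookup backed by :mod:`intervaltree`.

    Stores closed intervals with an attached payload and answers
    "anything overlapping [start, end]?" queries.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, payload=None) -> None:
        if start > end:
            raise ValueError(f"invalid interval ({start}, {end})")
        # half-open storage: closed [s, e] -> [s, e + 1)
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, payload)

    @classmethod
    def from_tuples(cls, rows: Sequence[tuple[str, int, int]]) -> "IntervalIndex":
        idx = cls()
        for chrom, s, e in rows:
            idx.add(chrom, s, e)
        return idx

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, object]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [(iv.begin, iv.end - 1, iv.data) for iv in tree.overlap(start, end + 1)]

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and bool(tree.overlap(start, end + 1))
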