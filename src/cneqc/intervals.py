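"""Genomic interval primitives.

All coordinates are 0-based half-open (BED convention); conversions from
1-based formats happen only in the format readers/writers.  Interval
arithmetic is strand-agnostic throughout: strand is carried as annotation
and never used in any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Interval",
    "IntervalSet",
    "merge_intervals",
    "subtract_intervals",
    "intersect_intervals",
    "overlap_length",
    "parse_bed",
    "write_bed",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class Interval:
    """A half-open span ``[start, end)`` on sequence ``seq_id``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unspecified).  ``name`` and
    ``extra`` hold optional BED columns 4 and 7+ verbatim.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("interval seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.seq_id, self.start, self.end)

    def overlaps(self, other: "Interval") -> bool:
        return overlap_length(self, other) > 0


def overlap_length(a: Interval, b: Interval) -> int:
    """Length of the intersection of two intervals; 0 if disjoint or on
    different sequences.  Half-open abutment ([0,100) vs [100,200)) is 0."""
    if a.seq_id != b.seq_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class IntervalSet:
    """An ordered collection of :class:`Interval`, sorted by
    ``(seq_id, start, end)``.  After :meth:`merge`, non-overlapping per
    sequence."""

    __slots__ = ("_intervals",)

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self._intervals: list[Interval] = sorted(intervals, key=Interval.sort_key)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    @property
    def seq_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.seq_id, None)
        return list(seen)

    def by_seq(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.seq_id, []).append(iv)
        return out

    def covered_bases(self) -> int:
        """Number of distinct bases covered (union, not sum of lengths)."""
        return sum(len(iv) for iv in self.merge(0))

    def merge(self, join_gap: int = 0) -> "IntervalSet":
        return merge_intervals(self, join_gap)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        return subtract_intervals(self, other)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        return intersect_intervals(self, other)


def merge_intervals(intervals: Iterable[Interval], join_gap: int = 0) -> IntervalSet:
    """Union intervals per sequence, additionally joining neighbours whose
    gap is <= ``join_gap``.

    The gap between ``[a,b)`` and ``[c,d)`` with ``c >= b`` is ``c - b``;
    abutting intervals have gap 0 and are joined at any ``join_gap >= 0``.
    Merged intervals drop name/strand annotation.
    """
    if join_gap < 0:
        raise ValueError("join_gap must be >= 0")
    merged: list[Interval] = []
    cur_seq: str | None = None
    cur_start = cur_end = 0
    for iv in sorted(intervals, key=Interval.sort_key):
        if iv.seq_id == cur_seq and iv.start - cur_end <= join_gap:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_seq is not None:
                merged.append(Interval(cur_seq, cur_start, cur_end))
            cur_seq, cur_start, cur_end = iv.seq_id, iv.start, iv.end
    if cur_seq is not None:
        merged.append(Interval(cur_seq, cur_start, cur_end))
    return IntervalSet(merged)


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> IntervalSet:
    """Base-wise difference ``covered(a) \\ covered(b)``.

    A single input interval may split into several fragments; fragments keep
    the annotation (strand/name/extra) of their source interval.
    """
    b_merged = merge_intervals(b, 0).by_seq()
    out: list[Interval] = []
    for iv in a:
        cuts = b_merged.get(iv.seq_id, ())
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos:
                continue
            if cut.start >= iv.end:
                break
            if cut.start > pos:
                out.append(replace(iv, start=pos, end=cut.start))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(replace(iv, start=pos, end=iv.end))
    return IntervalSet(out)


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> IntervalSet:
    """Base-wise intersection ``covered(a) ∩ covered(b)`` (merged output)."""
    a_m = merge_intervals(a, 0).by_seq()
    b_m = merge_intervals(b, 0).by_seq()
    out: list[Interval] = []
    for seq_id, avs in a_m.items():
        bvs = b_m.get(seq_id, [])
        i = j = 0
        while i < len(avs) and j < len(bvs):
            lo = max(avs[i].start, bvs[j].start)
            hi = min(avs[i].end, bvs[j].end)
            if lo < hi:
                out.append(Interval(seq_id, lo, hi))
            if avs[i].end < bvs[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


def parse_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file (tab-separated, 0-based half-open, no header).

    Column 4 is kept as ``name``, column 6 as ``strand``; any further
    columns are retained verbatim in ``extra``.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            seq_id = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate: {exc}"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            extra = tuple(fields[6:])
            intervals.append(Interval(seq_id, start, end, strand, name, extra))
    return IntervalSet(intervals)


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write BED; emits 3, 6 or 6+n columns depending on annotation present."""
    ivs = sorted(intervals, key=Interval.sort_key)
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.seq_id, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand != "." or iv.extra:
                fields += [iv.name if iv.name is not None else ".", "0", iv.strand]
                fields += list(iv.extra)
            fh.write("\t".join(fields) + "\n")
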