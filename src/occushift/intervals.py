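"""Genomic interval primitives and BED-level interval algebra.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  Two
intervals overlap iff they share at least one base; touching intervals
(``a.end == b.start``) do not overlap and are never merged.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Interval",
    "PeakSet",
    "MergedOS",
    "BedParseError",
    "read_bed",
    "write_bed",
    "sort_intervals",
    "intervals_overlap",
    "overlap_flags",
    "subtract_blacklist",
    "merge_union",
]


class BedParseError(ValueError):
    """Raised when a BED file cannot be parsed; the message names the line."""


@dataclass(frozen=True)
class Interval:
    """A genomic segment ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """A named collection of intervals, e.g. peak calls for one cell type."""

    cell_type: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sort_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class MergedOS:
    """A merged occupied segment: one row of the cross-cell-type atlas.

    ``members`` is the set of cell types whose original peak calls overlap
    the merged interval by at least one base.
    """

    interval: Interval
    os_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.os_id}: members must be non-empty")

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def sort_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    return sorted(intervals, key=Interval.sort_key)


def intervals_overlap(a: Interval, b: Interval) -> bool:
    """≥1 bp shared on the same chromosome (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def read_bed(path: str | Path, cell_type: str | None = None) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    Comment (``#``), ``track`` and ``browser`` lines are skipped.  Parse
    failures raise :class:`BedParseError` naming the 1-based line number.
    """
    path = Path(path)
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected ≥3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else None
            try:
                intervals.append(
                    Interval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(cell_type or path.stem, intervals)


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                cols.append(f"{iv.score:g}" if iv.score is not None else "0")
            if iv.strand is not None:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def _by_chrom(intervals: Sequence[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def overlap_flags(queries: Sequence[Interval], targets: Sequence[Interval]) -> list[bool]:
    """For each query interval, whether it overlaps ≥1 target by ≥1 bp.

    Sorted-sweep with a prefix-maximum of target ends; equivalent to the
    all-pairs check but O((n+m) log m).
    """
    targets_by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in _by_chrom(sort_intervals(targets)).items():
        starts = [iv.start for iv in ivs]
        prefix_max_end: list[int] = []
        running = -1
        for iv in ivs:
            running = max(running, iv.end)
            prefix_max_end.append(running)
        targets_by_chrom[chrom] = (starts, prefix_max_end)

    flags: list[bool] = []
    for q in queries:
        hit = False
        if q.chrom in targets_by_chrom:
            starts, prefix_max_end = targets_by_chrom[q.chrom]
            # candidates: targets with start < q.end
            hi = bisect.bisect_left(starts, q.end)
            if hi > 0 and prefix_max_end[hi - 1] > q.start:
                hit = True
        flags.append(hit)
    return flags


def subtract_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop every peak that overlaps any blacklist interval by ≥1 bp.

    Peaks are removed whole; surviving peaks are untouched.
    """
    flags = overlap_flags(peaks.intervals, blacklist.intervals)
    kept = [iv for iv, hit in zip(peaks.intervals, flags) if not hit]
    return PeakSet(peaks.cell_type, kept)


def merge_union(peaksets: Sequence[PeakSet], id_prefix: str = "OS") -> list[MergedOS]:
    """Concatenate peak sets and merge overlapping segments into one atlas.

    Output intervals are pairwise disjoint and sorted; each merged segment
    records the set of cell types contributing ≥1 overlapping original peak.
    Touching intervals are kept separate (overlap means ≥1 shared base).
    """
    tagged: list[tuple[Interval, str]] = []
    for ps in peaksets:
        for iv in ps.intervals:
            tagged.append((iv, ps.cell_type))
    tagged.sort(key=lambda t: t[0].sort_key())

    merged: list[MergedOS] = []
    cur: tuple[str, int, int, set[str]] | None = None

    def flush() -> None:
        if cur is not None:
            chrom, start, end, members = cur
            merged.append(
                MergedOS(
                    interval=Interval(chrom, start, end),
                    os_id="",  # assigned below
                    members=frozenset(members),
                )
            )

    for iv, ct in tagged:
        if cur is not None and iv.chrom == cur[0] and iv.start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end), cur[3] | {ct})
        else:
            flush()
            cur = (iv.chrom, iv.start, iv.end, {ct})
    flush()

    width = max(6, len(str(len(merged))))
    return [
        MergedOS(m.interval, f"{id_prefix}_{i:0{width}d}", m.members)
        for i, m in enumerate(merged)
    ]
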