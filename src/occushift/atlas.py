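"""Occupancy atlas: signal quantification, normalization, sharing partition.

The atlas is built by :func:`occushift.intervals.merge_union`; this module
attaches per-cell-type signal to the merged segments (mean per-base
coverage from bedGraph tracks, scaled to counts-per-million of each
track's total signal), quantile-normalizes the resulting matrix, and
partitions segments by their cross-cell-type sharing pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import MergedOS

__all__ = [
    "CoverageTrack",
    "OccupancyMatrix",
    "read_bedgraph",
    "count_signal",
    "quantile_normalize",
    "partition_by_sharing",
    "default_grouping_map",
    "DEFAULT_CELL_TYPES",
]

DEFAULT_CELL_TYPES = ("HPC7", "Epro", "G1E", "ER4", "Ebl", "Meg")


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping coverage records per chromosome.

    ``records[chrom] = (starts, ends, values)`` as numpy arrays.  Bases not
    covered by any record have value 0.
    """

    records: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @property
    def total_signal(self) -> float:
        """Sum over records of value × length (the track's 'library size')."""
        total = 0.0
        for starts, ends, values in self.records.values():
            total += float(np.sum(values * (ends - starts)))
        return total

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base coverage over [start, end); uncovered bases count 0."""
        if chrom not in self.records:
            return 0.0
        starts, ends, values = self.records[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        total = float(np.sum(values[lo:hi] * np.maximum(e - s, 0)))
        return total / (end - start)


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Parse a bedGraph file; records must be sortable and non-overlapping.

    Negative coverage values are rejected.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value {value}")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start ≥ end")
            per_chrom.setdefault(chrom, []).append((start, end, value))

    records: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=float)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: overlapping records on {chrom}")
        records[chrom] = (starts, ends, values)
    return CoverageTrack(records)


@dataclass
class OccupancyMatrix:
    """Merged segments × cell types signal matrix.

    ``raw_mean`` holds mean per-base coverage; ``cpm`` the library-
    normalized values (per-million of each track's total signal);
    ``normalized`` the quantile-normalized CPM matrix used for clustering.
    """

    os_ids: list[str]
    cell_types: list[str]
    raw_mean: pd.DataFrame
    cpm: pd.DataFrame
    membership: pd.DataFrame  # boolean, from original peak calls

    @property
    def normalized(self) -> pd.DataFrame:
        return quantile_normalize(self.cpm)


def count_signal(
    os_list: Sequence[MergedOS],
    coverage: Mapping[str, CoverageTrack],
) -> OccupancyMatrix:
    """Attach per-cell-type signal to merged segments.

    For each segment the raw value is the mean per-base coverage over the
    interval; the CPM value scales each column by 1e6 / total track signal,
    making columns comparable across sequencing depths.
    """
    cell_types = list(coverage.keys())
    os_ids = [os.os_id for os in os_list]
    raw = np.zeros((len(os_list), len(cell_types)))
    for j, ct in enumerate(cell_types):
        track = coverage[ct]
        for i, os in enumerate(os_list):
            raw[i, j] = track.mean_over(os.chrom, os.interval.start, os.interval.end)
    raw_df = pd.DataFrame(raw, index=os_ids, columns=cell_types)

    cpm = raw_df.copy()
    for ct in cell_types:
        total = coverage[ct].total_signal
        cpm[ct] = raw_df[ct] * (1e6 / total) if total > 0 else 0.0

    membership = pd.DataFrame(
        {ct: [ct in os.members for os in os_list] for ct in cell_types}, index=os_ids
    )
    return OccupancyMatrix(os_ids, cell_types, raw_df, cpm, membership)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-column mean reference distribution.

    Each column's sorted values are replaced by the mean, across columns, of
    the values at the same rank.  Ties within a column receive the mean of
    the reference values at their tied ranks (implemented by linear
    interpolation at the average rank).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs a non-empty matrix with ≥2 columns")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = pd.DataFrame(values).rank(method="average").to_numpy()  # 1..n, halves on ties
    n = values.shape[0]
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def default_grouping_map(
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
) -> dict[frozenset[str], str]:
    """The default sharing-pattern → group-name map.

    Covers the six single-cell-type categories plus the named shared
    categories (progenitor+early-erythroid, progenitor+megakaryocyte,
    the four-way erythroid set, and all six); unmapped patterns fall
    through to ``"other"``.
    """
    cts = list(cell_types)
    mapping: dict[frozenset[str], str] = {
        frozenset([ct]): f"{ct}_only" for ct in cts
    }
    named = {
        ("HPC7", "Epro"): "HPC7_Epro",
        ("HPC7", "Meg"): "HPC7_Meg",
        ("Epro", "G1E", "ER4", "Ebl"): "erythroid_shared",
    }
    for pattern, label in named.items():
        if all(ct in cts for ct in pattern):
            mapping[frozenset(pattern)] = label
    mapping[frozenset(cts)] = "all_shared"
    return mapping


def partition_by_sharing(
    os_list: Sequence[MergedOS],
    grouping_map: Mapping[frozenset[str], str] | Iterable[tuple[Iterable[str], str]] | None = None,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
) -> pd.Series:
    """Label each merged segment by its cross-cell-type sharing group.

    ``grouping_map`` maps membership patterns to named groups; patterns not
    in the map are labeled ``"other"``.  Conflicting entries (same pattern,
    different names) are rejected.
    """
    if grouping_map is None:
        grouping_map = default_grouping_map(cell_types)
    if not isinstance(grouping_map, Mapping):
        resolved: dict[frozenset[str], str] = {}
        for pattern, label in grouping_map:
            key = frozenset(pattern)
            if key in resolved and resolved[key] != label:
                raise ValueError(f"conflicting grouping-map entries for pattern {sorted(key)}")
            resolved[key] = label
        grouping_map = resolved
    else:
        grouping_map = {frozenset(k): v for k, v in grouping_map.items()}

    declared = set(cell_types)
    for pattern in grouping_map:
        if not pattern or not pattern <= declared:
            raise ValueError(
                f"grouping-map pattern {sorted(pattern)} is not a non-empty subset "
                f"of the declared cell types"
            )

    labels = [grouping_map.get(os.members, "other") for os in os_list]
    return pd.Series(labels, index=[os.os_id for os in os_list], name="sharing_group")
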