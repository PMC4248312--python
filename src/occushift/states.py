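"""Chromatin-state assignment and fate categorization across maturation.

Genome segmentations (nine histone-modification states, chromHMM-style)
are consumed as labeled BED tilings.  Each occupied segment is assigned
the state containing its midpoint; states collapse to an active/inactive
summary via a per-cell-type activity map (active = enriched for
H3K4me1/H3K4me3/H3K36me3; inactive = H3K27me3/H3K9me3/no modification).
Segments bound only in the progenitor cell type are then categorized by
their activity fate across the erythroid maturation series:

    (A,A,A) → active_all    (I,I,I) → inactive_all
    (A,A,I), (A,I,I) → progression (monotone inactivation)
    anything else → mixed
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import CoverageTrack
from .intervals import MergedOS

__all__ = [
    "StateSegmentation",
    "load_segmentation",
    "assign_state",
    "summarize_activity",
    "fate_categorize",
    "signal_summary",
    "DEFAULT_ACTIVITY_MAP",
]

# default for the shipped nine-label model: states 1-4 carry active marks
DEFAULT_ACTIVITY_MAP = {
    "state1": "active", "state2": "active", "state3": "active", "state4": "active",
    "state5": "inactive", "state6": "inactive", "state7": "inactive",
    "state8": "inactive", "state9": "inactive",
}


@dataclass
class StateSegmentation:
    """A complete labeled tiling of each chromosome for one cell type."""

    cell_type: str
    chroms: dict[str, tuple[np.ndarray, np.ndarray, list[str]]]  # starts, ends, labels

    def state_at(self, chrom: str, pos: int) -> str | None:
        if chrom not in self.chroms:
            return None
        starts, ends, labels = self.chroms[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and starts[i] <= pos < ends[i]:
            return labels[i]
        return None


def load_segmentation(path: str | Path, cell_type: str | None = None) -> StateSegmentation:
    """Read a state BED (name column = state label); validates the tiling
    (records on a chromosome must be contiguous and non-overlapping)."""
    from .intervals import read_bed

    peaks = read_bed(path)
    by_chrom: dict[str, list] = {}
    for iv in peaks.intervals:
        if iv.name is None:
            raise ValueError(f"{path}: state record without a label at {iv.chrom}:{iv.start}")
        by_chrom.setdefault(iv.chrom, []).append(iv)
    chroms = {}
    for chrom, ivs in by_chrom.items():
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start != prev.end:
                raise ValueError(
                    f"{path}: segmentation gap or overlap on {chrom} at {prev.end}..{cur.start}"
                )
        chroms[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
            [iv.name for iv in ivs],
        )
    return StateSegmentation(cell_type or Path(path).stem, chroms)


def assign_state(os: MergedOS, segmentation: StateSegmentation) -> str:
    """State of the segment containing the occupied segment's midpoint."""
    state = segmentation.state_at(os.chrom, os.midpoint)
    if state is None:
        raise ValueError(
            f"{os.os_id}: midpoint {os.chrom}:{os.midpoint} not covered by the "
            f"{segmentation.cell_type} segmentation"
        )
    return state


def summarize_activity(state: str, activity_map: Mapping[str, str]) -> str:
    if state not in activity_map:
        raise KeyError(f"unknown chromatin state {state!r}")
    activity = activity_map[state]
    if activity not in ("active", "inactive"):
        raise ValueError(f"activity for {state!r} must be 'active' or 'inactive'")
    return activity


def _categorize(acts: tuple[str, ...]) -> str:
    flags = tuple(a == "active" for a in acts)
    if all(flags):
        return "active_all"
    if not any(flags):
        return "inactive_all"
    if flags in ((True, True, False), (True, False, False)):
        return "progression"
    return "mixed"


def fate_categorize(
    os_list: Sequence[MergedOS],
    segmentations: Sequence[StateSegmentation],
    activity_maps: Sequence[Mapping[str, str]] | Mapping[str, str] = DEFAULT_ACTIVITY_MAP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Categorize each segment by its activity triple along the series.

    ``segmentations`` is the ordered maturation series (e.g. G1E → ER4 →
    Ebl); the series order is an argument, not a load order.  Returns the
    per-segment table and a category summary with counts and percentages.
    """
    if len(segmentations) != 3:
        raise ValueError("fate categorization is defined over a series of 3 cell types")
    if isinstance(activity_maps, Mapping):
        activity_maps = [activity_maps] * 3
    rows = []
    for os in os_list:
        states = tuple(assign_state(os, seg) for seg in segmentations)
        acts = tuple(
            summarize_activity(s, amap) for s, amap in zip(states, activity_maps)
        )
        row: dict = {"os_id": os.os_id}
        for seg, s, a in zip(segmentations, states, acts):
            row[f"state_{seg.cell_type}"] = s
            row[f"activity_{seg.cell_type}"] = a
        row["category"] = _categorize(acts)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("os_id") if rows else pd.DataFrame()

    categories = ["active_all", "inactive_all", "progression", "mixed"]
    counts = {c: int((table["category"] == c).sum()) if len(rows) else 0 for c in categories}
    total = sum(counts.values())
    summary = pd.DataFrame(
        {
            "count": [counts[c] for c in categories],
            "percent": [100.0 * counts[c] / total if total else 0.0 for c in categories],
        },
        index=pd.Index(categories, name="category"),
    )
    return table, summary


def signal_summary(
    os_list: Sequence[MergedOS],
    coverage: Mapping[str, CoverageTrack],
) -> pd.DataFrame:
    """Five-number summary of per-segment mean coverage per track.

    ``coverage`` maps a (mark, cell type) key to its track; the summary
    row order follows the mapping.
    """
    rows = []
    for key, track in coverage.items():
        means = np.array(
            [track.mean_over(os.chrom, os.interval.start, os.interval.end) for os in os_list]
        )
        if len(means) == 0:
            continue
        q = np.quantile(means, [0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append(
            {"track": key, "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
             "n_os": len(means)}
        )
    return pd.DataFrame(rows, columns=["track", "min", "q1", "median", "q3", "max", "n_os"])
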