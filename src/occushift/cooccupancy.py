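"""TF–TF co-occupancy fractions and the GATA1-response partition.

The response partition classifies each segment of the G1E/ER4 occupancy
universe by what TAL1 does when GATA1 is restored (dissociation,
retention, recruitment) and whether GATA1 itself co-occupies the segment
in ER4 cells (direct vs indirect effect):

    (TAL1-G1E, TAL1-ER4, GATA1-ER4) → group
    (T, F, F) → a   indirect dissociation
    (T, F, T) → b   direct dissociation
    (T, T, F) → c   indirect retention
    (T, T, T) → d   direct retention
    (F, T, F) → e   indirect recruitment
    (F, T, T) → f   direct recruitment
    (F, F, T) → gata1_only
    (F, F, F) → none

GATA switch sites are segments bound by GATA2 in G1E cells and by GATA1
in ER4 cells; GATA2 loss sites lose GATA2 without GATA1 replacement.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .intervals import Interval, MergedOS, PeakSet, overlap_flags

__all__ = [
    "RESPONSE_GROUPS",
    "overlap_fraction",
    "venn_partition",
    "classify_switch",
    "switch_crosstab",
]

RESPONSE_GROUPS: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "a",
    (True, False, True): "b",
    (True, True, False): "c",
    (True, True, True): "d",
    (False, True, False): "e",
    (False, True, True): "f",
    (False, False, True): "gata1_only",
    (False, False, False): "none",
}


def _intervals_of(x: PeakSet | Sequence[MergedOS] | Sequence[Interval]) -> list[Interval]:
    if isinstance(x, PeakSet):
        return list(x.intervals)
    out = []
    for item in x:
        out.append(item.interval if isinstance(item, MergedOS) else item)
    return out


def overlap_fraction(a, b) -> float:
    """Fraction of A's intervals overlapping ≥1 interval of B by ≥1 bp."""
    ivs_a = _intervals_of(a)
    if not ivs_a:
        warnings.warn("overlap_fraction: empty query set, returning 0", stacklevel=2)
        return 0.0
    flags = overlap_flags(ivs_a, _intervals_of(b))
    return sum(flags) / len(flags)


def venn_partition(
    os_list: Sequence[MergedOS],
    tal1_g1e_peaks: PeakSet,
    tal1_er4_peaks: PeakSet,
    gata1_er4_peaks: PeakSet,
) -> pd.DataFrame:
    """Response-partition each segment by the three occupancy booleans.

    Returns a frame indexed by os_id with columns tal1_g1e, tal1_er4,
    gata1_er4 (≥1 bp overlap each) and the derived group letter.
    """
    ivs = [os.interval for os in os_list]
    g1e = overlap_flags(ivs, tal1_g1e_peaks.intervals)
    er4 = overlap_flags(ivs, tal1_er4_peaks.intervals)
    gata1 = overlap_flags(ivs, gata1_er4_peaks.intervals)
    rows = {
        os.os_id: {
            "tal1_g1e": a,
            "tal1_er4": b,
            "gata1_er4": c,
            "group": RESPONSE_GROUPS[(a, b, c)],
        }
        for os, a, b, c in zip(os_list, g1e, er4, gata1)
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_switch(
    os_list: Sequence[MergedOS],
    gata2_g1e_peaks: PeakSet,
    gata1_er4_peaks: PeakSet,
) -> pd.DataFrame:
    """Label segments as GATA switch, GATA2 loss, or neither."""
    ivs = [os.interval for os in os_list]
    gata2 = overlap_flags(ivs, gata2_g1e_peaks.intervals)
    gata1 = overlap_flags(ivs, gata1_er4_peaks.intervals)
    rows = {
        os.os_id: {
            "gata2_g1e": a,
            "gata1_er4": b,
            "label": "switch" if (a and b) else ("loss" if a else "none"),
        }
        for os, a, b in zip(os_list, gata2, gata1)
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def switch_crosstab(partition: pd.DataFrame, switch: pd.DataFrame) -> pd.DataFrame:
    """Response group × switch label contingency table (all groups kept).

    Row sums equal the per-group segment counts.
    """
    joined = partition[["group"]].join(switch[["label"]], how="inner")
    tab = pd.crosstab(joined["group"], joined["label"])
    for col in ("switch", "loss", "none"):
        if col not in tab.columns:
            tab[col] = 0
    return tab[["switch", "loss", "none"]]
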