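"""Presumptive target-gene assignment for occupied segments.

Two standard rules: all genes whose TSS lies in the same
enhancer-promoter unit (EPU) as the segment midpoint; or the single gene
with the nearest TSS on the same chromosome.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .intervals import Interval, MergedOS, read_bed

__all__ = [
    "Gene",
    "EPU",
    "TargetMap",
    "load_genes",
    "load_epus",
    "assign_by_epu",
    "assign_nearest_tss",
]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS")


@dataclass(frozen=True)
class EPU:
    epu_id: str
    interval: Interval


@dataclass
class TargetMap:
    """os_id → assigned target genes, with per-segment flags."""

    method: str  # "epu" or "nearest"
    targets: dict[str, list[str]]
    flags: dict[str, str] = field(default_factory=dict)  # os_id → flag text

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "os_id": os_id,
                "method": self.method,
                "gene_ids": ";".join(genes),
                "flag": self.flags.get(os_id, ""),
            }
            for os_id, genes in self.targets.items()
        ]
        return pd.DataFrame(rows, columns=["os_id", "method", "gene_ids", "flag"])


def load_genes(path: str | Path) -> list[Gene]:
    """Read a TSS BED (name=gene_id, strand in column 6).

    A gene with several annotated TSSs contributes one record per TSS.
    The TSS coordinate is the interval start (records are 1-bp points).
    """
    peaks = read_bed(path)
    genes = []
    for iv in peaks.intervals:
        if iv.name is None:
            raise ValueError(f"{path}: TSS record without a gene name at {iv.chrom}:{iv.start}")
        genes.append(Gene(gene_id=iv.name, chrom=iv.chrom, tss=iv.start,
                          strand=iv.strand or "+"))
    return genes


def load_epus(path: str | Path) -> list[EPU]:
    """Read an EPU BED; overlapping EPUs are rejected at load."""
    peaks = read_bed(path)
    epus = []
    prev: Interval | None = None
    for i, iv in enumerate(peaks.intervals):
        if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
            raise ValueError(f"{path}: overlapping EPUs at {iv.chrom}:{iv.start}")
        epus.append(EPU(epu_id=iv.name or f"EPU_{i:04d}", interval=iv))
        prev = iv
    return epus


def _epu_index(epus: Sequence[EPU]) -> dict[str, tuple[list[int], list[EPU]]]:
    by_chrom: dict[str, list[EPU]] = {}
    for e in sorted(epus, key=lambda e: e.interval.sort_key()):
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    return {c: ([e.interval.start for e in es], es) for c, es in by_chrom.items()}


def containing_epu(epus_index, chrom: str, pos: int) -> EPU | None:
    if chrom not in epus_index:
        return None
    starts, es = epus_index[chrom]
    i = bisect.bisect_right(starts, pos) - 1
    if i >= 0 and es[i].interval.start <= pos < es[i].interval.end:
        return es[i]
    return None


def assign_by_epu(
    os_list: Sequence[MergedOS],
    epus: Sequence[EPU],
    genes: Sequence[Gene],
) -> TargetMap:
    """All genes whose TSS falls in the EPU containing the segment midpoint.

    Segments outside every EPU (or in a gene-free EPU) get an empty target
    list and a flag.  Target lists contain no duplicate gene ids.
    """
    index = _epu_index(epus)
    genes_by_epu: dict[str, list[str]] = {}
    for g in genes:
        epu = containing_epu(index, g.chrom, g.tss)
        if epu is not None:
            genes_by_epu.setdefault(epu.epu_id, []).append(g.gene_id)

    targets: dict[str, list[str]] = {}
    flags: dict[str, str] = {}
    for os in os_list:
        epu = containing_epu(index, os.chrom, os.midpoint)
        if epu is None:
            targets[os.os_id] = []
            flags[os.os_id] = "outside_epu"
        else:
            seen: list[str] = []
            for gid in genes_by_epu.get(epu.epu_id, []):
                if gid not in seen:
                    seen.append(gid)
            targets[os.os_id] = seen
            if not seen:
                flags[os.os_id] = "gene_free_epu"
    return TargetMap(method="epu", targets=targets, flags=flags)


def assign_nearest_tss(os_list: Sequence[MergedOS], genes: Sequence[Gene]) -> TargetMap:
    """The gene with the TSS nearest the segment midpoint (same chromosome).

    Distance is unsigned; exact ties go to the lexicographically smaller
    gene_id and are flagged.  Segments on a chromosome without genes are
    flagged unassigned.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: (g.tss, g.gene_id))

    targets: dict[str, list[str]] = {}
    flags: dict[str, str] = {}
    for os in os_list:
        gs = by_chrom.get(os.chrom, [])
        if not gs:
            targets[os.os_id] = []
            flags[os.os_id] = "no_gene_on_chrom"
            continue
        mid = os.midpoint
        tss_list = [g.tss for g in gs]
        i = bisect.bisect_left(tss_list, mid)
        # candidates around the insertion point, plus neighbours sharing a TSS
        cand_idx = {j for j in (i - 1, i, i + 1) if 0 <= j < len(gs)}
        best_d = min(abs(gs[j].tss - mid) for j in cand_idx)
        ties = sorted(
            g.gene_id for g in gs if abs(g.tss - mid) == best_d
        )
        targets[os.os_id] = [ties[0]]
        if len(ties) > 1:
            flags[os.os_id] = "tie"
    return TargetMap(method="nearest", targets=targets, flags=flags)
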