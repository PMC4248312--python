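"""Synthetic fixture generation with planted, recoverable ground truth.

Every downstream stage of the pipeline is exercised on miniature data
emitted by this module: an i.i.d. background genome, per-cell-type peak
calls with controlled cross-cell-type sharing, motif words planted with
tunable centrality inside segment-centered windows, coverage tracks
(Poisson background plus a Gaussian-shaped bump over each peak),
enhancer-promoter units and TSS annotation, chromatin-state tilings, and
an expression table whose induced/repressed labels are coupled to the
planted occupancy-response groups.  A JSON manifest records the truth:
the planted sharing pattern and response group per peak, every planted
motif offset, and each gene's expression label.

All randomness flows from one seeded generator; identical config + seed
reproduces a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .atlas import DEFAULT_CELL_TYPES, CoverageTrack
from .cooccupancy import RESPONSE_GROUPS
from .intervals import Interval, PeakSet, write_bed
from .motifs import BASES, PWM, pwm_from_consensus
from .states import DEFAULT_ACTIVITY_MAP
from .targets import EPU, Gene, containing_epu, _epu_index

__all__ = [
    "MotifSpec",
    "FixtureConfig",
    "PlantedOS",
    "PlantedMotif",
    "Genome",
    "FixtureBundle",
    "builtin_pwms",
    "generate_genome",
    "plant_peaks",
    "plant_motifs",
    "synthesize_coverage",
    "generate_regulatory_annotation",
    "generate_expression",
    "generate_bundle",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    pwm_id: str
    planting_rate: float  # probability a segment receives one planted word
    central_fraction: float  # probability the word is placed centrally
    central_halfwidth: int = 50

    def __post_init__(self) -> None:
        for p, name in ((self.planting_rate, "planting_rate"),
                        (self.central_fraction, "central_fraction")):
            if not 0 <= p <= 1:
                raise ValueError(f"{self.pwm_id}: {name} must be in [0,1], got {p}")
        if self.central_halfwidth <= 0:
            raise ValueError(f"{self.pwm_id}: central_halfwidth must be > 0")


def _default_sharing() -> dict[tuple[str, ...], int]:
    return {
        ("HPC7",): 120,
        ("Epro",): 60,
        ("G1E",): 80,
        ("ER4",): 80,
        ("Ebl",): 60,
        ("Meg",): 60,
        ("HPC7", "Epro"): 30,
        ("HPC7", "Meg"): 30,
        ("Epro", "G1E", "ER4", "Ebl"): 60,
        ("HPC7", "Epro", "G1E", "ER4", "Ebl", "Meg"): 10,
    }


def _default_motif_spec() -> list[MotifSpec]:
    return [
        MotifSpec("GATA", 0.8, 0.75, 50),
        MotifSpec("EBOX", 0.5, 0.60, 50),
        MotifSpec("ETS", 0.3, 0.30, 50),
        MotifSpec("RUNX", 0.3, 0.30, 50),
        MotifSpec("KLF", 0.3, 0.0, 50),
    ]


def _default_coupling() -> dict[str, tuple[float, float]]:
    # direct retention/recruitment (d, f) couple to induction; dissociation
    # (a, b) couples to repression; indirect-only groups are near baseline
    return {
        "a": (0.05, 0.45),
        "b": (0.05, 0.50),
        "c": (0.08, 0.08),
        "d": (0.60, 0.05),
        "e": (0.08, 0.08),
        "f": (0.55, 0.05),
        "gata1_only": (0.30, 0.10),
    }


@dataclass
class FixtureConfig:
    """Everything the generator needs; defaults define the demo fixture."""

    n_chroms: int = 2
    chrom_length: int = 500_000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    sharing_spec: dict[tuple[str, ...], int] = field(default_factory=_default_sharing)
    peak_width: int = 300
    peak_width_jitter: int = 60
    coord_jitter: int = 20
    slot_length: int = 1200  # exclusive placement slot per planted event
    motif_spec: list[MotifSpec] = field(default_factory=_default_motif_spec)
    cooccupancy_spec: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {"GATA2_G1E": ("G1E", 0.5)}
    )
    # P(GATA1 co-occupancy in ER4 | TAL1 in G1E, TAL1 in ER4) — defaults give
    # direct:indirect odds comparable to the published group sizes
    gata1_prob: dict[tuple[bool, bool], float] = field(
        default_factory=lambda: {
            (True, False): 0.37, (True, True): 0.93, (False, True): 0.76,
            (False, False): 0.05,
        }
    )
    n_gata1_only: int = 20
    response_coupling: dict[str, tuple[float, float]] = field(default_factory=_default_coupling)
    baseline_de: tuple[float, float] = (0.10, 0.10)
    n_genes: int = 300
    n_epus: int = 40
    epu_gap: int = 2_000
    intergenic_gene_fraction: float = 0.05
    state_cell_types: tuple[str, ...] = ("G1E", "ER4", "Ebl")
    state_labels: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ACTIVITY_MAP))
    state_active_prob: float | Mapping[str, float] = 0.6
    gc_fraction: float = 0.45
    background_rate: float = 1.0
    peak_amplitude: float = 20.0
    coverage_bin: int = 10
    n_blacklist: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length <= 0:
            raise ValueError("need ≥1 chromosome of positive length")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be > 0")
        if self.chrom_length < 10 * self.peak_width:
            raise ValueError("chrom_length must be ≥ 10 × peak_width")
        declared = set(self.cell_types)
        for pattern, count in self.sharing_spec.items():
            if not pattern or not set(pattern) <= declared:
                raise ValueError(
                    f"sharing pattern {pattern} is not a non-empty subset of cell types"
                )
            if count < 0:
                raise ValueError(f"negative count for pattern {pattern}")
        for probs in self.gata1_prob.values():
            if not 0 <= probs <= 1:
                raise ValueError("gata1_prob values must be in [0,1]")
        for group, (p_ind, p_rep) in self.response_coupling.items():
            if p_ind < 0 or p_rep < 0 or p_ind + p_rep > 1:
                raise ValueError(
                    f"coupling for group {group!r}: p_induced + p_repressed must be ≤ 1"
                )
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be ≥ 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


# ---------------------------------------------------------------------------
# Ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class PlantedOS:
    """One planting event: a peak shared across the cell types of its pattern.

    Exposes ``os_id``/``chrom``/``midpoint``/``interval`` so planted events
    can stand in for merged segments in window extraction and assignment.
    """

    uid: str
    pattern: tuple[str, ...]
    chrom: str
    start: int  # canonical union coordinates over the pattern's cell types
    end: int
    per_cell_type: dict[str, tuple[int, int]]
    tal1_g1e: bool
    tal1_er4: bool
    gata1_er4: bool
    gata2_g1e: bool
    group: str

    @property
    def os_id(self) -> str:
        return self.uid

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, name=self.uid)


@dataclass(frozen=True)
class PlantedMotif:
    uid: str  # planted event
    pwm_id: str
    offset: float  # word midpoint relative to event midpoint (scanner convention)
    strand: str
    word: str
    central: bool


@dataclass
class FixtureBundle:
    """Paths of an emitted fixture plus its in-memory ground truth."""

    root: Path
    genome_fasta: Path
    peak_beds: dict[str, Path]
    partner_beds: dict[str, Path]
    coverage_bedgraphs: dict[str, Path]
    pwm_files: dict[str, Path]
    blacklist_bed: Path
    epu_bed: Path
    tss_bed: Path
    expression_tsv: Path
    state_beds: dict[str, Path]
    manifest_json: Path
    config: FixtureConfig
    manifest: list[PlantedOS]
    motif_manifest: list[PlantedMotif]
    gene_labels: pd.Series


# ---------------------------------------------------------------------------
# PWMs shipped with the generator
# ---------------------------------------------------------------------------

def builtin_pwms() -> dict[str, PWM]:
    """Synthetic consensus-derived example PWMs for the five motif families.

    Illustrative stand-ins built from the families' published consensus
    cores (GATA WGATAA, E-box CAGVTG, ETS GGAWGT core, RUNX TGYGGT core,
    KLF GC-box); they are not curated database matrices.
    """
    return {
        "GATA": pwm_from_consensus("GATA", "WGATAA", match_prob=0.92),
        "EBOX": pwm_from_consensus("EBOX", "CAGVTG", match_prob=0.92),
        "ETS": pwm_from_consensus("ETS", "GGAWGT", match_prob=0.90),
        "RUNX": pwm_from_consensus("RUNX", "TGYGGT", match_prob=0.90),
        "KLF": pwm_from_consensus("KLF", "GGGGCGGGG", match_prob=0.88),
    }


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """In-memory genome as per-chromosome base-code arrays (A=0..T=3)."""

    seqs: dict[str, np.ndarray]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def as_strings(self) -> dict[str, str]:
        lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
        return {c: lut[s].tobytes().decode("ascii") for c, s in self.seqs.items()}

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.as_strings().items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        return path

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Genome":
        code = np.full(256, 4, dtype=np.uint8)
        for i, b in enumerate(BASES):
            code[ord(b)] = i
            code[ord(b.lower())] = i
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            arr = np.frombuffer(str(rec.seq).encode("ascii"), dtype=np.uint8)
            seqs[rec.id] = code[arr].copy()
        return cls(seqs)


def generate_genome(config: FixtureConfig, rng: np.random.Generator | None = None) -> Genome:
    """I.i.d. background sequence at the configured GC fraction."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {
        chrom: rng.choice(4, size=config.chrom_length, p=probs).astype(np.uint8)
        for chrom in config.chrom_names
    }
    return Genome(seqs)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def plant_peaks(
    config: FixtureConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, PeakSet], dict[str, PeakSet], PeakSet, list[PlantedOS]]:
    """Plant peaks with the configured sharing structure.

    Each planting event occupies its own placement slot, so planted events
    never merge with each other.  Returns (TAL1 peak sets per cell type,
    partner-TF peak sets, blacklist, manifest).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    slot = config.slot_length
    min_width = config.peak_width - config.peak_width_jitter
    if min_width <= 0:
        raise ValueError("peak_width_jitter must leave positive widths")
    if slot < config.peak_width + config.peak_width_jitter + 2 * config.coord_jitter + 20:
        raise ValueError("slot_length too small for the configured peak width and jitter")

    all_slots = [
        (chrom, s * slot)
        for chrom in config.chrom_names
        for s in range(config.chrom_length // slot)
    ]
    n_events = sum(config.sharing_spec.values())
    needed = n_events + config.n_gata1_only + config.n_blacklist
    if needed > len(all_slots):
        raise ValueError(
            f"genome too small: {needed} placement slots requested, "
            f"{len(all_slots)} available (slot={slot} bp)"
        )
    chosen = rng.choice(len(all_slots), size=needed, replace=False)
    chosen_slots = [all_slots[i] for i in chosen]

    patterns: list[tuple[str, ...] | None] = []
    for pattern, count in config.sharing_spec.items():
        patterns.extend([tuple(pattern)] * count)
    patterns.extend([None] * config.n_gata1_only)  # GATA1-only events
    patterns = [patterns[i] for i in rng.permutation(len(patterns))]

    center_jitter_cap = min(
        80, max(0, (slot - config.peak_width - 2 * config.coord_jitter) // 2 - 10)
    )
    tal1: dict[str, list[Interval]] = {ct: [] for ct in config.cell_types}
    gata1_intervals: list[Interval] = []
    partner_intervals: dict[str, list[Interval]] = {name: [] for name in config.cooccupancy_spec}
    manifest: list[PlantedOS] = []

    def jittered(center: int, width: int, chrom_len: int) -> tuple[int, int]:
        j = config.coord_jitter
        s = center - width // 2 + int(rng.integers(-j, j + 1)) if j else center - width // 2
        e = center + (width - width // 2) + (int(rng.integers(-j, j + 1)) if j else 0)
        s = max(0, s)
        e = min(chrom_len, max(e, s + 1))
        return s, e

    for idx, ((chrom, slot_start), pattern) in enumerate(zip(chosen_slots[:len(patterns)], patterns)):
        center = slot_start + slot // 2
        if center_jitter_cap:
            center += int(rng.integers(-center_jitter_cap, center_jitter_cap + 1))
        width = config.peak_width + (
            int(rng.integers(-config.peak_width_jitter, config.peak_width_jitter + 1))
            if config.peak_width_jitter else 0
        )

        if pattern is None:  # GATA1-only event
            s, e = jittered(center, width, config.chrom_length)
            gata1_intervals.append(Interval(chrom, s, e))
            manifest.append(
                PlantedOS(
                    uid=f"P{idx:05d}", pattern=(), chrom=chrom, start=s, end=e,
                    per_cell_type={}, tal1_g1e=False, tal1_er4=False,
                    gata1_er4=True, gata2_g1e=False, group="gata1_only",
                )
            )
            continue

        per_ct: dict[str, tuple[int, int]] = {}
        for ct in config.cell_types:
            if ct in pattern:
                per_ct[ct] = jittered(center, width, config.chrom_length)
                tal1[ct].append(Interval(chrom, *per_ct[ct]))
        start = min(s for s, _ in per_ct.values())
        end = max(e for _, e in per_ct.values())

        g1e, er4 = "G1E" in pattern, "ER4" in pattern
        gata1 = bool(rng.random() < config.gata1_prob.get((g1e, er4), 0.0))
        if gata1:
            gata1_intervals.append(Interval(chrom, *jittered(center, width, config.chrom_length)))

        gata2 = False
        for name, (host_ct, prob) in config.cooccupancy_spec.items():
            if host_ct in pattern and rng.random() < prob:
                partner_intervals[name].append(
                    Interval(chrom, *jittered(center, width, config.chrom_length))
                )
                if name == "GATA2_G1E":
                    gata2 = True

        manifest.append(
            PlantedOS(
                uid=f"P{idx:05d}", pattern=pattern, chrom=chrom, start=start, end=end,
                per_cell_type=per_ct, tal1_g1e=g1e, tal1_er4=er4,
                gata1_er4=gata1, gata2_g1e=gata2,
                group=RESPONSE_GROUPS[(g1e, er4, gata1)],
            )
        )

    blacklist = [
        Interval(chrom, s + slot // 2 - 250, s + slot // 2 + 250)
        for chrom, s in chosen_slots[len(patterns):]
    ]

    tal1_sets = {ct: PeakSet(ct, ivs) for ct, ivs in tal1.items()}
    partner_sets = {name: PeakSet(name, ivs) for name, ivs in partner_intervals.items()}
    partner_sets["GATA1_ER4"] = PeakSet("GATA1_ER4", gata1_intervals)
    return tal1_sets, partner_sets, PeakSet("blacklist", blacklist), manifest


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def _sample_word(pwm: PWM, rng: np.random.Generator) -> np.ndarray:
    """Consensus-weighted sampling: draw each position from the PWM column."""
    return np.array(
        [rng.choice(4, p=pwm.probs[i]) for i in range(pwm.width)], dtype=np.uint8
    )


_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def plant_motifs(
    genome: Genome,
    manifest: Sequence[PlantedOS],
    motif_spec: Sequence[MotifSpec],
    pwms: Mapping[str, PWM],
    rng: np.random.Generator | None = None,
    window: int = 1000,
    seed: int | None = None,
    max_retries: int = 30,
) -> list[PlantedMotif]:
    """Write sampled motif words into segment-centered windows in place.

    For each planted segment and each motif spec, with probability
    ``planting_rate`` a word is written at a central offset (within
    ±central_halfwidth of the midpoint) with probability
    ``central_fraction``, else uniformly in the window.  Colliding plants
    are re-drawn up to ``max_retries`` times, then skipped.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    half = window // 2
    occupied: dict[str, list[tuple[int, int]]] = {}
    planted: list[PlantedMotif] = []

    for spec in motif_spec:
        pwm = pwms[spec.pwm_id]
        if pwm.width >= spec.central_halfwidth * 2:
            raise ValueError(
                f"{spec.pwm_id}: motif width {pwm.width} too large for the "
                f"central window (halfwidth {spec.central_halfwidth})"
            )

    for event in manifest:
        seq = genome.seqs[event.chrom]
        mid = event.midpoint
        for spec in motif_spec:
            if spec.planting_rate == 0 or rng.random() >= spec.planting_rate:
                continue
            pwm = pwms[spec.pwm_id]
            w = pwm.width
            placed = False
            for _ in range(max_retries):
                central = bool(rng.random() < spec.central_fraction)
                if central:
                    hw = spec.central_halfwidth
                    if w % 2 == 1:
                        target = int(rng.integers(-hw, hw + 1))
                        start_rel = target - (w - 1) // 2
                    else:
                        target = int(rng.integers(-hw, hw))  # offset = target + 0.5
                        start_rel = target - w // 2 + 1
                else:
                    start_rel = int(rng.integers(-half, half - w + 1))
                start = mid + start_rel
                if start < 0 or start + w > len(seq):
                    continue
                span = (start, start + w)
                if any(s < span[1] and span[0] < e for s, e in occupied.get(event.chrom, [])):
                    continue
                word = _sample_word(pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                written = word if strand == "+" else _COMPLEMENT[word[::-1]]
                seq[start:start + w] = written
                occupied.setdefault(event.chrom, []).append(span)
                planted.append(
                    PlantedMotif(
                        uid=event.uid,
                        pwm_id=spec.pwm_id,
                        offset=start_rel + (w - 1) / 2.0,
                        strand=strand,
                        word="".join(BASES[b] for b in word),
                        central=central,
                    )
                )
                placed = True
                break
            if not placed:
                continue
    return planted


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def synthesize_coverage(
    peaksets: Mapping[str, PeakSet],
    chrom_lengths: Mapping[str, int],
    background_rate: float = 1.0,
    amplitude: float = 20.0,
    bin_size: int = 10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, CoverageTrack]:
    """Poisson background plus a Gaussian bump over each peak.

    Coverage is piecewise constant on ``bin_size`` bins; the bump sigma is
    a quarter of the peak width.  Negative amplitudes are rejected.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be ≥ 0")
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    tracks: dict[str, CoverageTrack] = {}
    for ct, peaks in peaksets.items():
        records: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        peaks_by_chrom: dict[str, list[Interval]] = {}
        for iv in peaks.intervals:
            peaks_by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, length in chrom_lengths.items():
            nb = math.ceil(length / bin_size)
            values = rng.poisson(background_rate, size=nb).astype(float)
            centers = (np.arange(nb) + 0.5) * bin_size
            for iv in peaks_by_chrom.get(chrom, []):
                c = (iv.start + iv.end) / 2.0
                sigma = max(iv.length / 4.0, 1.0)
                lo = max(0, int((c - 4 * sigma) // bin_size))
                hi = min(nb, int((c + 4 * sigma) // bin_size) + 1)
                x = centers[lo:hi]
                values[lo:hi] += amplitude * np.exp(-0.5 * ((x - c) / sigma) ** 2)
            values = np.round(values, 3)
            # run-length encode equal consecutive bins
            change = np.nonzero(np.diff(values))[0] + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [nb]])
            starts = run_starts * bin_size
            ends = np.minimum(run_ends * bin_size, length)
            vals = values[run_starts]
            records[chrom] = (starts.astype(np.int64), ends.astype(np.int64), vals)
        tracks[ct] = CoverageTrack(records)
    return tracks


def write_bedgraph(track: CoverageTrack, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(track.records):
            starts, ends, values = track.records[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    return path


# ---------------------------------------------------------------------------
# Regulatory annotation: EPUs, genes, chromatin states
# ---------------------------------------------------------------------------

def generate_regulatory_annotation(
    config: FixtureConfig, rng: np.random.Generator | None = None
) -> tuple[list[EPU], list[Gene], dict[str, "object"]]:
    """Non-overlapping EPUs with gaps, gene TSSs, and state tilings.

    Every chromosome is completely tiled by the nine state labels in each
    state cell type; a fraction of genes is placed in the inter-EPU gaps
    (intergenic).
    """
    from .states import StateSegmentation

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gap = config.epu_gap
    epus: list[EPU] = []
    per_chrom = _split_count(config.n_epus, config.n_chroms)
    for chrom, k in zip(config.chrom_names, per_chrom):
        if k == 0:
            continue
        block = (config.chrom_length - (k + 1) * gap) // k
        if block <= 100:
            raise ValueError("chromosome too short for the requested EPU count and gap")
        for i in range(k):
            start = gap + i * (block + gap)
            epus.append(EPU(f"{chrom}_EPU{i:03d}", Interval(chrom, start, start + block)))

    genes: list[Gene] = []
    n_intergenic = int(round(config.n_genes * config.intergenic_gene_fraction))
    n_genic = config.n_genes - n_intergenic
    for gi in range(n_genic):
        epu = epus[int(rng.integers(0, len(epus)))]
        tss = int(rng.integers(epu.interval.start + 10, epu.interval.end - 10))
        genes.append(Gene(f"g{gi:04d}", epu.interval.chrom, tss,
                          "+" if rng.random() < 0.5 else "-"))
    for gi in range(n_genic, config.n_genes):
        # place in a gap before a random EPU
        epu = epus[int(rng.integers(0, len(epus)))]
        tss = int(rng.integers(max(0, epu.interval.start - gap + 10), epu.interval.start - 5))
        genes.append(Gene(f"g{gi:04d}", epu.interval.chrom, tss,
                          "+" if rng.random() < 0.5 else "-"))

    active_states = sorted(s for s, a in config.state_labels.items() if a == "active")
    inactive_states = sorted(s for s, a in config.state_labels.items() if a == "inactive")
    segmentations: dict[str, StateSegmentation] = {}
    for ct in config.state_cell_types:
        p_active = (
            config.state_active_prob.get(ct, 0.6)
            if isinstance(config.state_active_prob, Mapping)
            else config.state_active_prob
        )
        chroms = {}
        for chrom in config.chrom_names:
            starts, ends, labels = [], [], []
            pos = 0
            while pos < config.chrom_length:
                seg_len = int(rng.integers(1_000, 5_000))
                end = min(pos + seg_len, config.chrom_length)
                pool = active_states if rng.random() < p_active else inactive_states
                labels.append(pool[int(rng.integers(0, len(pool)))])
                starts.append(pos)
                ends.append(end)
                pos = end
            chroms[chrom] = (
                np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64), labels
            )
        segmentations[ct] = StateSegmentation(ct, chroms)
    return epus, genes, segmentations


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: FixtureConfig,
    manifest: Sequence[PlantedOS],
    epus: Sequence[EPU],
    genes: Sequence[Gene],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression table whose DE labels are coupled to occupancy groups.

    Each gene's governing segment is the response-labeled planted segment
    nearest its TSS within the same EPU; the gene is drawn induced /
    repressed / not_DE from that group's coupling probabilities (baseline
    probabilities when no segment targets it).  Emitted (log2 FPKM pair,
    q-value) rows reproduce the label exactly under the DE rule.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    index = _epu_index(epus)
    events_by_epu: dict[str, list[PlantedOS]] = {}
    for ev in manifest:
        if ev.group == "none":
            continue
        epu = containing_epu(index, ev.chrom, ev.midpoint)
        if epu is not None:
            events_by_epu.setdefault(epu.epu_id, []).append(ev)

    rows = []
    labels = {}
    for gene in genes:
        epu = containing_epu(index, gene.chrom, gene.tss)
        governing: PlantedOS | None = None
        if epu is not None:
            candidates = events_by_epu.get(epu.epu_id, [])
            if candidates:
                governing = min(
                    candidates, key=lambda ev: (abs(ev.midpoint - gene.tss), ev.uid)
                )
        if governing is None:
            p_ind, p_rep = config.baseline_de
        else:
            p_ind, p_rep = config.response_coupling.get(governing.group, config.baseline_de)
        u = rng.random()
        label = "induced" if u < p_ind else ("repressed" if u < p_ind + p_rep else "not_DE")
        labels[gene.gene_id] = label
        a, b, q = _realize_expression(label, rng)
        rows.append({"gene_id": gene.gene_id, "log2_fpkm_a": a, "log2_fpkm_b": b, "q_value": q})
    table = pd.DataFrame(rows, columns=["gene_id", "log2_fpkm_a", "log2_fpkm_b", "q_value"])
    return table, pd.Series(labels, name="label")


def _realize_expression(label: str, rng: np.random.Generator) -> tuple[float, float, float]:
    """(log2 FPKM A, log2 FPKM B, q) reproducing the label under the DE rule."""
    if label == "induced":
        a = round(float(rng.uniform(3.5, 6.0)), 3)
        b = round(a + float(rng.uniform(1.0, 3.0)), 3)
        q = round(float(rng.uniform(0.001, 0.045)), 3)
    elif label == "repressed":
        a = round(float(rng.uniform(4.6, 7.0)), 3)
        b = round(a - float(rng.uniform(1.0, a - 3.5)), 3)
        q = round(float(rng.uniform(0.001, 0.045)), 3)
    else:  # not_DE: either fails FDR while active, or fails the activity floor
        if rng.random() < 0.5:
            a = round(float(rng.uniform(3.5, 6.0)), 3)
            b = round(a + float(rng.uniform(-0.4, 2.0)), 3)
            q = round(float(rng.uniform(0.06, 0.95)), 3)
        else:
            a = round(float(rng.uniform(-2.0, 2.8)), 3)
            b = round(float(rng.uniform(-2.0, 6.0)), 3)
            q = round(float(rng.uniform(0.0, 1.0)), 3)
    return a, b, q


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

def _write_jaspar(pwm: PWM, path: Path, scale: int = 1000) -> Path:
    counts = np.rint(pwm.probs * scale).astype(int)
    with open(path, "w") as fh:
        fh.write(f">{pwm.pwm_id}\n")
        for bi, base in enumerate(BASES):
            nums = " ".join(str(int(c)) for c in counts[:, bi])
            fh.write(f"{base} [ {nums} ]\n")
    return path


def generate_bundle(config: FixtureConfig, outdir: str | Path) -> FixtureBundle:
    """Emit the complete fixture bundle under ``outdir``.

    Deterministic: identical config + seed produce byte-identical files.
    """
    outdir = Path(outdir)
    for sub in ("peaks", "partners", "coverage", "pwms", "states"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(config.seed)
    # independent, reproducible streams per stage
    stage_seeds = {name: int(master.integers(0, 2**31 - 1))
                   for name in ("genome", "peaks", "motifs", "coverage",
                                "annotation", "expression")}

    genome = generate_genome(config, np.random.default_rng(stage_seeds["genome"]))
    tal1_sets, partner_sets, blacklist, manifest = plant_peaks(
        config, np.random.default_rng(stage_seeds["peaks"])
    )
    pwms = builtin_pwms()
    motif_manifest = plant_motifs(
        genome, manifest, config.motif_spec, pwms,
        np.random.default_rng(stage_seeds["motifs"]),
    )
    tracks = synthesize_coverage(
        tal1_sets, genome.lengths(),
        background_rate=config.background_rate,
        amplitude=config.peak_amplitude,
        bin_size=config.coverage_bin,
        rng=np.random.default_rng(stage_seeds["coverage"]),
    )
    epus, genes, segmentations = generate_regulatory_annotation(
        config, np.random.default_rng(stage_seeds["annotation"])
    )
    expression, gene_labels = generate_expression(
        config, manifest, epus, genes, np.random.default_rng(stage_seeds["expression"])
    )

    genome_fasta = genome.write_fasta(outdir / "genome.fa")
    peak_beds = {}
    for ct, ps in tal1_sets.items():
        peak_beds[ct] = outdir / "peaks" / f"{ct}.bed"
        write_bed(ps.intervals, peak_beds[ct])
    partner_beds = {}
    for name, ps in partner_sets.items():
        partner_beds[name] = outdir / "partners" / f"{name}.bed"
        write_bed(ps.intervals, partner_beds[name])
    blacklist_bed = outdir / "blacklist.bed"
    write_bed(blacklist.intervals, blacklist_bed)
    coverage_paths = {}
    for ct, track in tracks.items():
        coverage_paths[ct] = outdir / "coverage" / f"{ct}.bedGraph"
        write_bedgraph(track, coverage_paths[ct])
    pwm_files = {pid: _write_jaspar(p, outdir / "pwms" / f"{pid}.jaspar")
                 for pid, p in pwms.items()}
    epu_bed = outdir / "epus.bed"
    write_bed([dataclasses.replace(e.interval, name=e.epu_id) for e in epus], epu_bed)
    tss_bed = outdir / "tss.bed"
    write_bed(
        [Interval(g.chrom, g.tss, g.tss + 1, name=g.gene_id, score=0.0, strand=g.strand)
         for g in genes],
        tss_bed,
    )
    expression_tsv = outdir / "expression.tsv"
    expression.to_csv(expression_tsv, sep="\t", index=False)
    state_beds = {}
    for ct, seg in segmentations.items():
        state_beds[ct] = outdir / "states" / f"{ct}_states.bed"
        with open(state_beds[ct], "w") as fh:
            for chrom in sorted(seg.chroms):
                starts, ends, seg_labels = seg.chroms[chrom]
                for s, e, lab in zip(starts, ends, seg_labels):
                    fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")

    manifest_json = outdir / "manifest.json"
    manifest_payload = {
        "seed": config.seed,
        "cell_types": list(config.cell_types),
        "events": [
            {
                "uid": ev.uid, "pattern": list(ev.pattern), "chrom": ev.chrom,
                "start": ev.start, "end": ev.end,
                "per_cell_type": {ct: list(se) for ct, se in ev.per_cell_type.items()},
                "tal1_g1e": ev.tal1_g1e, "tal1_er4": ev.tal1_er4,
                "gata1_er4": ev.gata1_er4, "gata2_g1e": ev.gata2_g1e,
                "group": ev.group,
            }
            for ev in manifest
        ],
        "motifs": [
            {"uid": m.uid, "pwm_id": m.pwm_id, "offset": m.offset,
             "strand": m.strand, "word": m.word, "central": m.central}
            for m in motif_manifest
        ],
        "gene_labels": gene_labels.to_dict(),
        "state_activity": dict(config.state_labels),
    }
    with open(manifest_json, "w") as fh:
        json.dump(manifest_payload, fh, indent=1, sort_keys=True)

    return FixtureBundle(
        root=outdir,
        genome_fasta=genome_fasta,
        peak_beds=peak_beds,
        partner_beds=partner_beds,
        coverage_bedgraphs=coverage_paths,
        pwm_files=pwm_files,
        blacklist_bed=blacklist_bed,
        epu_bed=epu_bed,
        tss_bed=tss_bed,
        expression_tsv=expression_tsv,
        state_beds=state_beds,
        manifest_json=manifest_json,
        config=config,
        manifest=manifest,
        motif_manifest=motif_manifest,
        gene_labels=gene_labels,
    )
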