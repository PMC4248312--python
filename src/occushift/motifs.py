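"""PWM scanning and central-window motif enrichment.

Scoring follows the FIMO design: per-position log-odds scores (bits,
against a background base composition) are discretized onto a common
integer grid; the null distribution of the total score of a random
background word is computed exactly by dynamic programming over that
grid, and both the p-value threshold and the scanner operate on the same
integer scores, so threshold decisions are exact with respect to the
grid.  Grid granularity is 1/1000 of the total score range.

The enrichment statistic compares motif density in the central window
(default ±50 bp around the segment midpoint) against the flanks of the
1-kb window, each normalized by the same quantity measured on comparably
sized random genomic segments:

    log2 OR = log2( (a/c) / (b/d) )

with a,b = mean central/flank counts per occupied segment and c,d the
same means over random segments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .intervals import Interval

__all__ = [
    "PWM",
    "MotifInstance",
    "ScoreThreshold",
    "Window",
    "MotifCountQuad",
    "EnrichmentResult",
    "read_pwm",
    "pwm_from_consensus",
    "score_threshold",
    "extract_windows",
    "scan",
    "random_segments",
    "central_enrichment",
    "position_histogram",
    "dotplot_matrix",
]

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
SCORE_GRANULARITY = 1000  # grid steps spanning the total score range

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class PWM:
    """Position probability matrix with a background model.

    ``probs`` is width × 4 (A, C, G, T), rows summing to 1.
    """

    pwm_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"{self.pwm_id}: probs must be width × 4")
        if self.width < 4:
            raise ValueError(f"{self.pwm_id}: width must be ≥ 4, got {self.width}")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.pwm_id}: probability rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.pwm_id}: background must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError(
                f"{self.pwm_id}: zero probabilities; supply a pseudocount at load time"
            )

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p/background) score matrix (bits)."""
        return np.log2(self.probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def scaled_scores(self, granularity: int = SCORE_GRANULARITY) -> tuple[np.ndarray, float, float]:
        """Integer score matrix, plus (offset, delta) to map back to bits.

        Real score of a word ≈ sum(ints) * delta + offset; per-position
        scores are shifted so the position minimum maps to 0.
        """
        lo = self.log_odds
        row_min = lo.min(axis=1, keepdims=True)
        total_range = float((lo.max(axis=1) - lo.min(axis=1)).sum())
        delta = total_range / granularity if total_range > 0 else 1.0
        ints = np.rint((lo - row_min) / delta).astype(np.int64)
        offset = float(row_min.sum())
        return ints, offset, delta


@dataclass(frozen=True)
class MotifInstance:
    """A motif match in a segment-centered window.

    ``offset`` is the matched word's midpoint relative to the segment
    midpoint (symmetric under strand, so half-integer for even widths).
    """

    os_id: str
    offset: float
    strand: str
    score: float


@dataclass(frozen=True)
class ScoreThreshold:
    pwm_id: str
    pvalue_target: float
    int_threshold: int
    score: float  # bits
    pvalue_attained: float
    offset: float
    delta: float


@dataclass(frozen=True)
class Window:
    """A sequence window centered (nominally) on a segment midpoint."""

    os_id: str
    seq: str
    start_offset: int  # offset of seq[0] relative to the segment midpoint
    clipped: bool = False


@dataclass(frozen=True)
class MotifCountQuad:
    a: float  # mean central count per occupied segment
    b: float  # mean flank count per occupied segment
    c: float  # mean central count per random segment
    d: float  # mean flank count per random segment
    n_os: int
    n_random: int

    def __post_init__(self) -> None:
        if self.n_os <= 0 or self.n_random <= 0:
            raise ValueError("n_os and n_random must be positive")
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("count means must be ≥ 0")


@dataclass(frozen=True)
class EnrichmentResult:
    pwm_id: str
    quad: MotifCountQuad
    log2_odds_ratio: float
    epsilon_applied: bool


# ---------------------------------------------------------------------------
# PWM input
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path, pseudocount: float = 0.01,
             background: Sequence[float] | None = None) -> PWM:
    """Read a JASPAR count matrix or MEME-minimal motif file.

    Counts (JASPAR) are converted to probabilities with the pseudocount
    added per cell; MEME letter-probability rows are regularized the same
    way.  Background defaults to uniform unless supplied.
    """
    text = Path(path).read_text()
    if "letter-probability matrix" in text:
        pwm_id, matrix = _parse_meme_minimal(text)
    else:
        pwm_id, matrix = _parse_jaspar(text)
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0):
        raise ValueError(f"{path}: negative matrix entries")
    row_sums = matrix.sum(axis=1)
    if pseudocount <= 0 and np.any(matrix == 0):
        raise ValueError(f"{path}: zero entries require a positive pseudocount")
    if np.any(row_sums + 4 * pseudocount <= 0):
        raise ValueError(f"{path}: empty matrix row")
    probs = (matrix + pseudocount) / (row_sums + 4 * pseudocount)[:, None]
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return PWM(pwm_id=pwm_id, probs=probs, background=bg, pseudocount=pseudocount)


def _parse_jaspar(text: str) -> tuple[str, np.ndarray]:
    """JASPAR 4-row layout: one line per base, counts in brackets or bare."""
    pwm_id = "pwm"
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            pwm_id = line[1:].split()[0]
            continue
        m = re.match(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]+?)\s*\]?$", line)
        if not m:
            raise ValueError(f"unparseable JASPAR line: {line!r}")
        base, numbers = m.group(1), m.group(2).split()
        rows[base] = [float(x) for x in numbers]
    if set(rows) != set(BASES):
        raise ValueError(f"JASPAR matrix missing base rows (got {sorted(rows)})")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise ValueError("ragged JASPAR matrix: base rows have unequal widths")
    return pwm_id, np.array([rows[b] for b in BASES], dtype=float).T


def _parse_meme_minimal(text: str) -> tuple[str, np.ndarray]:
    pwm_id = "pwm"
    rows: list[list[float]] = []
    in_matrix = False
    expected_w: int | None = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) > 1:
                pwm_id = parts[1]
        elif line.startswith("letter-probability matrix"):
            in_matrix = True
            m = re.search(r"w=\s*(\d+)", line)
            expected_w = int(m.group(1)) if m else None
        elif in_matrix:
            if not line or line.startswith("URL"):
                break
            vals = [float(x) for x in line.split()]
            if len(vals) != 4:
                raise ValueError(f"ragged MEME matrix row: {line!r}")
            rows.append(vals)
    if not rows:
        raise ValueError("no letter-probability matrix found")
    if expected_w is not None and len(rows) != expected_w:
        raise ValueError(f"MEME matrix has {len(rows)} rows, header says w={expected_w}")
    return pwm_id, np.array(rows, dtype=float)


def pwm_from_consensus(pwm_id: str, consensus: str, match_prob: float = 0.9,
                       background: Sequence[float] | None = None) -> PWM:
    """Build a synthetic PWM from an IUPAC consensus string.

    Probability mass ``match_prob`` is split over the consensus bases at
    each position, the remainder over the others.  These are illustrative
    stand-ins for database matrices, not curated motifs.
    """
    w = len(consensus)
    probs = np.zeros((w, 4))
    for i, letter in enumerate(consensus.upper()):
        allowed = IUPAC.get(letter)
        if not allowed:
            raise ValueError(f"unknown IUPAC letter {letter!r}")
        others = [b for b in BASES if b not in allowed]
        for b in allowed:
            probs[i, _BASE_CODE[b]] = match_prob / len(allowed)
        rest = 1.0 - match_prob
        for b in others:
            probs[i, _BASE_CODE[b]] = rest / len(others) if others else 0.0
        if not others:  # letter covers all four bases
            probs[i] = np.full(4, 0.25)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return PWM(pwm_id=pwm_id, probs=probs, background=bg)


# ---------------------------------------------------------------------------
# Exact p-value threshold
# ---------------------------------------------------------------------------

def score_threshold(pwm: PWM, p: float = 1e-3,
                    granularity: int = SCORE_GRANULARITY) -> ScoreThreshold:
    """Smallest score t with P(random background word scores ≥ t) ≤ p.

    Exact dynamic programming over the discretized per-position score
    distributions under the PWM's background model.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0, 1], got {p}")
    ints, offset, delta = pwm.scaled_scores(granularity)
    pmf = np.array([1.0])
    for i in range(pwm.width):
        width_i = int(ints[i].max()) + 1
        pos = np.zeros(width_i)
        for b in range(4):
            pos[ints[i, b]] += pwm.background[b]
        pmf = np.convolve(pmf, pos)
    tail = np.cumsum(pmf[::-1])[::-1]
    # smallest achievable score whose tail probability is ≤ p
    candidates = np.nonzero((tail <= p) & (pmf > 0))[0]
    t = int(candidates[0]) if len(candidates) else len(pmf)  # len(pmf): unattainable
    attained = float(tail[t]) if t < len(pmf) else 0.0
    return ScoreThreshold(
        pwm_id=pwm.pwm_id,
        pvalue_target=p,
        int_threshold=t,
        score=t * delta + offset,
        pvalue_attained=attained,
        offset=offset,
        delta=delta,
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str, honor_mask: bool) -> np.ndarray:
    """A/C/G/T → 0..3; N, other letters and (optionally) soft-masked
    lowercase → 4 (never matched)."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for i, ch in enumerate(seq):
        if honor_mask and ch.islower():
            continue
        code = _BASE_CODE.get(ch.upper())
        if code is not None:
            out[i] = code
    return out


def extract_windows(
    genome: Mapping[str, str],
    os_list: Sequence,
    radius: int = 500,
) -> list[Window]:
    """1-kb (2 × radius) windows centered on segment midpoints.

    Windows running past a chromosome edge are truncated to the available
    span and flagged ``clipped``.
    """
    windows: list[Window] = []
    for os in os_list:
        chrom = os.chrom
        if chrom not in genome:
            raise KeyError(f"{os.os_id}: chromosome {chrom!r} not in genome")
        seq = genome[chrom]
        mid = os.midpoint
        lo, hi = mid - radius, mid + radius
        clipped = lo < 0 or hi > len(seq)
        lo_c, hi_c = max(lo, 0), min(hi, len(seq))
        windows.append(Window(os_id=os.os_id, seq=seq[lo_c:hi_c],
                              start_offset=lo_c - mid, clipped=clipped))
    return windows


def scan(
    windows: Sequence[Window],
    pwm: PWM,
    threshold: ScoreThreshold,
    honor_mask: bool = False,
) -> list[MotifInstance]:
    """Report every position × strand whose integer score meets the threshold.

    Overlapping matches are all reported; word positions containing an
    ambiguous base (or soft-masked base when ``honor_mask``) are skipped.
    The minus strand is scored with the reverse-complement matrix, which
    shares the threshold's integer grid exactly.
    """
    ints, offset, delta = pwm.scaled_scores()
    w = pwm.width
    rc_ints = ints[::-1, ::-1]  # reverse positions, complement bases
    instances: list[MotifInstance] = []
    for window in windows:
        codes = _encode(window.seq, honor_mask)
        n = len(codes)
        if n < w:
            continue
        view = np.lib.stride_tricks.sliding_window_view(codes, w)  # (n-w+1, w)
        valid = np.all(view < 4, axis=1)
        safe = np.where(view < 4, view, 0)
        cols = np.arange(w)
        fwd = ints[cols, safe].sum(axis=1)
        rev = rc_ints[cols, safe].sum(axis=1)
        for strand, scores in (("+", fwd), ("-", rev)):
            hits = np.nonzero(valid & (scores >= threshold.int_threshold))[0]
            for j in hits:
                instances.append(
                    MotifInstance(
                        os_id=window.os_id,
                        offset=window.start_offset + j + (w - 1) / 2.0,
                        strand=strand,
                        score=float(scores[j]) * delta + offset,
                    )
                )
    return instances


def random_segments(
    genome: Mapping[str, str],
    n: int,
    length: int = 1000,
    seed: int | np.random.Generator = 0,
    blacklist: Sequence[Interval] = (),
    max_attempts_factor: int = 50,
) -> list[Interval]:
    """n uniform-random, non-blacklisted windows of fixed length."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = [c for c in genome if len(genome[c]) >= length]
    if not chroms:
        raise ValueError(f"no chromosome is ≥ {length} bp")
    capacity = np.array([len(genome[c]) - length + 1 for c in chroms], dtype=float)
    probs = capacity / capacity.sum()
    bl_by_chrom: dict[str, list[Interval]] = {}
    for iv in blacklist:
        bl_by_chrom.setdefault(iv.chrom, []).append(iv)

    out: list[Interval] = []
    attempts = 0
    while len(out) < n:
        if attempts > max_attempts_factor * max(n, 1):
            raise ValueError("cannot place requested random segments outside the blacklist")
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        candidate = Interval(chrom, start, start + length)
        if any(candidate.start < b.end and b.start < candidate.end
               for b in bl_by_chrom.get(chrom, [])):
            continue
        out.append(candidate)
    return out


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def central_enrichment(
    instances: Sequence[MotifInstance],
    n_os: int,
    random_instances: Sequence[MotifInstance],
    n_random: int,
    halfwidth: int = 50,
    window: int = 1000,
    pwm_id: str = "",
) -> EnrichmentResult:
    """log2 odds ratio of central vs flank motif density, random-normalized.

    A match is central when its midpoint offset lies within ±halfwidth of
    the segment midpoint.  When any of the four count means is zero, a
    small epsilon (1 / (n_random × window)) is added to all four and the
    result is flagged.
    """
    if n_os <= 0 or n_random <= 0:
        raise ValueError("n_os and n_random must be positive")

    def split(inst: Sequence[MotifInstance]) -> tuple[int, int]:
        central = sum(1 for m in inst if abs(m.offset) <= halfwidth)
        flank = sum(1 for m in inst if halfwidth < abs(m.offset) <= window / 2)
        return central, flank

    ca, fa = split(instances)
    cr, fr = split(random_instances)
    quad = MotifCountQuad(a=ca / n_os, b=fa / n_os, c=cr / n_random, d=fr / n_random,
                          n_os=n_os, n_random=n_random)
    a, b, c, d = quad.a, quad.b, quad.c, quad.d
    eps_applied = min(a, b, c, d) == 0
    if eps_applied:
        eps = 1.0 / (n_random * window)
        a, b, c, d = a + eps, b + eps, c + eps, d + eps
    log2_or = float(np.log2((a / c) / (b / d)))
    return EnrichmentResult(pwm_id=pwm_id, quad=quad,
                            log2_odds_ratio=log2_or, epsilon_applied=eps_applied)


def position_histogram(
    instances: Sequence[MotifInstance],
    binsize: int = 20,
    window: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offset histogram plus a kernel-density curve over the window.

    Returns (bin_edges, counts, density); counts sum to the number of
    instances and the density integrates to 1 (all-zero when empty).
    """
    if window % binsize != 0:
        raise ValueError(f"binsize {binsize} must divide the window width {window}")
    half = window // 2
    edges = np.arange(-half, half + binsize, binsize, dtype=float)
    offsets = np.array([m.offset for m in instances], dtype=float)
    counts, _ = np.histogram(offsets, bins=edges)
    grid = (edges[:-1] + edges[1:]) / 2.0
    if len(offsets) > 1 and np.std(offsets) > 0:
        density = gaussian_kde(offsets)(grid)
        density = density / np.trapezoid(density, grid) if np.trapezoid(density, grid) > 0 else density
    else:
        density = np.zeros_like(grid)
    return edges, counts, density


def dotplot_matrix(
    instances: Sequence[MotifInstance],
    occupancy_strength: Mapping[str, float],
) -> pd.DataFrame:
    """Occupancy-sorted dot-plot data: one row per instance.

    Segments are ranked by ascending occupancy strength (ties broken by
    os_id); output rows are ordered by rank then offset.
    """
    missing = sorted({m.os_id for m in instances} - set(occupancy_strength))
    if missing:
        raise KeyError(f"no occupancy strength for os_ids: {missing}")
    ranked = sorted(occupancy_strength.items(), key=lambda kv: (kv[1], kv[0]))
    rank_of = {os_id: r for r, (os_id, _) in enumerate(ranked)}
    rows = sorted(
        (
            {"rank": rank_of[m.os_id], "os_id": m.os_id, "offset": m.offset,
             "strand": m.strand, "strength": occupancy_strength[m.os_id]}
            for m in instances
        ),
        key=lambda r: (r["rank"], r["offset"], r["strand"]),
    )
    return pd.DataFrame(rows, columns=["rank", "os_id", "offset", "strand", "strength"])
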