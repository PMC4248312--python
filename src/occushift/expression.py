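"""Expression-response analysis with a label-shuffling permutation null.

Differential expression is declared from a precomputed table: a gene is
DE when it is actively expressed in both conditions (log2 FPKM > 3) and
passes FDR ≤ 0.05; induced/repressed by direction of change.  Per-segment
induced/repressed percentages over assigned target genes are averaged
within response groups, and enrichment against the pooled background is
calibrated by shuffling the group designation across segments (group
sizes preserved) and recomputing, 1000 times by default:

    log2( true group mean % / shuffled pseudo-mean % )
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .targets import TargetMap

__all__ = [
    "ResponseSummary",
    "read_expression_table",
    "classify_de",
    "os_response_fractions",
    "group_means",
    "permutation_null",
]

DIRECTIONS = ("induced", "repressed")
EPSILON_PCT = 0.01  # percentage points, guards log2 of a zero pseudo-mean


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id, log2_fpkm_a, log2_fpkm_b, q_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2_fpkm_a", "log2_fpkm_b", "q_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def classify_de(
    table: pd.DataFrame, active_threshold: float = 3.0, fdr: float = 0.05
) -> pd.DataFrame:
    """Attach induced/repressed/not_DE labels under the stated DE rule.

    DE requires log2 FPKM > active_threshold in both conditions and
    q ≤ fdr; a DE call with exactly equal FPKMs is demoted to not_DE and
    flagged.
    """
    q = table["q_value"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q_value outside [0, 1]")
    a = table["log2_fpkm_a"].to_numpy(dtype=float)
    b = table["log2_fpkm_b"].to_numpy(dtype=float)
    de = (a > active_threshold) & (b > active_threshold) & (q <= fdr)
    label = np.where(de & (b > a), "induced", np.where(de & (b < a), "repressed", "not_DE"))
    out = table.copy()
    out["label"] = label
    out["flag"] = np.where(de & (a == b), "de_no_direction", "")
    return out


def os_response_fractions(
    target_map: TargetMap,
    labels: pd.Series,
    denominator: str = "all",
) -> tuple[pd.DataFrame, int]:
    """Per-segment induced/repressed percentages over assigned targets.

    ``denominator="all"`` uses every assigned target gene;
    ``denominator="de"`` uses only DE targets.  Segments whose denominator
    is zero are excluded; the exclusion count is returned alongside.
    """
    if denominator not in ("all", "de"):
        raise ValueError(f"denominator must be 'all' or 'de', got {denominator!r}")
    rows = []
    excluded = 0
    for os_id, genes in target_map.targets.items():
        lab = [labels.get(g, "not_DE") for g in genes]
        n_ind = sum(1 for x in lab if x == "induced")
        n_rep = sum(1 for x in lab if x == "repressed")
        denom = len(lab) if denominator == "all" else (n_ind + n_rep)
        if denom == 0:
            excluded += 1
            continue
        rows.append(
            {
                "os_id": os_id,
                "n_targets": len(lab),
                "pct_induced": 100.0 * n_ind / denom,
                "pct_repressed": 100.0 * n_rep / denom,
            }
        )
    df = pd.DataFrame(rows, columns=["os_id", "n_targets", "pct_induced", "pct_repressed"])
    return df.set_index("os_id"), excluded


def group_means(fractions: pd.DataFrame, partition: pd.Series) -> pd.DataFrame:
    """Unweighted mean of per-segment percentages within each group.

    Groups present in ``partition`` but with no segment carrying fractions
    are reported with n=0 and NaN means.
    """
    joined = fractions.join(partition.rename("group"), how="inner")
    out_rows = []
    for group in sorted(partition.unique()):
        sub = joined[joined["group"] == group]
        out_rows.append(
            {
                "group": group,
                "n_os": len(sub),
                "mean_pct_induced": float(sub["pct_induced"].mean()) if len(sub) else float("nan"),
                "mean_pct_repressed": float(sub["pct_repressed"].mean()) if len(sub) else float("nan"),
            }
        )
    return pd.DataFrame(out_rows).set_index("group")


@dataclass
class ResponseSummary:
    """Permutation-calibrated group enrichment for induction/repression."""

    true_means: pd.DataFrame  # group × (mean_pct_induced, mean_pct_repressed, n_os)
    pseudo_means: dict[str, np.ndarray]  # group → (n_perm, 2) pseudo-mean matrix
    log2_ratios: dict[str, np.ndarray]  # group → (n_perm, 2) log2(true/pseudo)
    background: pd.DataFrame  # group × direction mean pseudo-mean (dotted lines)
    pvalues: pd.DataFrame  # group × direction empirical two-sided p
    n_perm: int
    seed: int
    epsilon_flags: dict[str, list[str]] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for group in self.true_means.index:
            for di, direction in enumerate(DIRECTIONS):
                rows.append(
                    {
                        "group": group,
                        "direction": direction,
                        "true_pct": self.true_means.loc[group, f"mean_pct_{direction}"],
                        "background_pct": self.background.loc[group, direction],
                        "mean_log2_ratio": float(np.mean(self.log2_ratios[group][:, di])),
                        "p_value": self.pvalues.loc[group, direction],
                    }
                )
        return pd.DataFrame(rows)


def permutation_null(
    fractions: pd.DataFrame,
    partition: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> ResponseSummary:
    """Shuffle group designations across segments and recompute group means.

    Group sizes are preserved exactly (labels are permuted, target lists
    stay attached to their segments).  Per group and direction the
    pseudo-mean distribution, its mean (the background line), the
    log2(true/pseudo) distribution and an add-one-smoothed empirical
    two-sided p-value (extremeness measured from the pseudo-mean center)
    are reported.  Zero pseudo-means are guarded with a small epsilon in
    percentage points and flagged.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    joined = fractions.join(partition.rename("group"), how="inner")
    if joined.empty:
        raise ValueError("no segments carry both fractions and a group label")
    groups = sorted(joined["group"].unique())
    code_of = {g: i for i, g in enumerate(groups)}
    codes = joined["group"].map(code_of).to_numpy()
    values = joined[["pct_induced", "pct_repressed"]].to_numpy(dtype=float)
    counts = np.bincount(codes, minlength=len(groups)).astype(float)

    true_means = pd.DataFrame(
        {
            "mean_pct_induced": np.bincount(codes, weights=values[:, 0], minlength=len(groups)) / counts,
            "mean_pct_repressed": np.bincount(codes, weights=values[:, 1], minlength=len(groups)) / counts,
            "n_os": counts.astype(int),
        },
        index=pd.Index(groups, name="group"),
    )

    rng = np.random.default_rng(seed)
    pseudo = np.empty((n_perm, len(groups), 2))
    for p in range(n_perm):
        perm_codes = rng.permutation(codes)
        for di in range(2):
            pseudo[p, :, di] = (
                np.bincount(perm_codes, weights=values[:, di], minlength=len(groups)) / counts
            )

    pseudo_means = {g: pseudo[:, code_of[g], :].copy() for g in groups}
    background = pd.DataFrame(
        pseudo.mean(axis=0), index=pd.Index(groups, name="group"), columns=list(DIRECTIONS)
    )

    log2_ratios: dict[str, np.ndarray] = {}
    epsilon_flags: dict[str, list[str]] = {}
    true_arr = true_means[["mean_pct_induced", "mean_pct_repressed"]].to_numpy()
    for g in groups:
        gi = code_of[g]
        num = np.broadcast_to(true_arr[gi], (n_perm, 2)).copy()
        den = pseudo[:, gi, :].copy()
        flagged = []
        for di, direction in enumerate(DIRECTIONS):
            if np.any(den[:, di] == 0) or num[0, di] == 0:
                num[:, di] += EPSILON_PCT
                den[:, di] += EPSILON_PCT
                flagged.append(direction)
        log2_ratios[g] = np.log2(num / den)
        if flagged:
            epsilon_flags[g] = flagged

    pvals = pd.DataFrame(index=pd.Index(groups, name="group"), columns=list(DIRECTIONS), dtype=float)
    for g in groups:
        gi = code_of[g]
        for di, direction in enumerate(DIRECTIONS):
            dist = pseudo[:, gi, di]
            center = dist.mean()
            extreme = np.sum(np.abs(dist - center) >= abs(true_arr[gi, di] - center))
            pvals.loc[g, direction] = (extreme + 1) / (n_perm + 1)

    return ResponseSummary(
        true_means=true_means,
        pseudo_means=pseudo_means,
        log2_ratios=log2_ratios,
        background=background,
        pvalues=pvals,
        n_perm=n_perm,
        seed=seed,
        epsilon_flags=epsilon_flags,
    )
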