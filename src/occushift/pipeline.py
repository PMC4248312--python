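"""End-to-end orchestration from a declarative YAML config.

Stages run in dependency order (atlas → clustering / motifs /
co-occupancy → targets → expression response → chromatin states); every
output file's content hash is recorded in a provenance manifest, so a
rerun with identical config and seeds reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import clustering as clustering_mod
from . import cooccupancy as cooc_mod
from . import expression as expr_mod
from . import motifs as motifs_mod
from . import states as states_mod
from . import targets as targets_mod
from .intervals import MergedOS, PeakSet, merge_union, read_bed, subtract_blacklist, write_bed
from .simulate import Genome

logger = logging.getLogger("occushift")

__all__ = ["PipelineConfig", "ConfigError", "StageError", "validate_config", "run", "ALL_STAGES"]

ALL_STAGES = ("atlas", "cluster", "motifs", "cooccupancy", "targets", "response", "states")

_STAGE_DEPS: dict[str, tuple[str, ...]] = {
    "atlas": (),
    "cluster": ("atlas",),
    "motifs": ("atlas",),
    "cooccupancy": (),
    "targets": ("atlas",),
    "response": ("cooccupancy",),
    "states": ("atlas",),
}

_PARAM_DEFAULTS: dict[str, float | int] = {
    "k": 16,
    "n_restarts": 10,
    "motif_p": 1e-3,
    "halfwidth": 50,
    "window": 1000,
    "n_perm": 1000,
    "active_threshold": 3.0,
    "fdr": 0.05,
    "min_overlap": 1,
    "seed": 0,
    "clip_lo": 0.005,
    "clip_hi": 0.995,
}

_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "k": (1, 1e9),
    "n_restarts": (1, 1e9),
    "motif_p": (1e-12, 1.0),
    "halfwidth": (1, 1e9),
    "window": (2, 1e9),
    "n_perm": (1, 1e9),
    "fdr": (0.0, 1.0),
    "min_overlap": (1, 1e9),
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the offending key."""


class StageError(RuntimeError):
    """A pipeline stage failed; downstream dependents are not run."""


@dataclass
class PipelineConfig:
    outdir: Path
    genome_fasta: Path | None
    peaks: dict[str, Path]
    coverage: dict[str, Path]
    blacklist: Path | None
    partners: dict[str, Path]
    pwms: dict[str, Path]
    epus: Path | None
    tss: Path | None
    expression: Path | None
    states: dict[str, Path]
    series_order: list[str]
    cell_types: list[str]
    params: dict[str, float | int]
    grouping_map: dict[str, list[str]] | None = None
    source: Path | None = None

    def effective(self) -> dict:
        """The full effective configuration (for logging/provenance)."""
        def _p(v):
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, dict):
                return {k: _p(x) for k, x in v.items()}
            return v
        return {k: _p(v) for k, v in self.__dict__.items() if k != "source"}


def _as_path_map(raw, base: Path, key: str) -> dict[str, Path]:
    if raw is None:
        return {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{key}: expected a mapping of name → path")
    out = {}
    for name, p in raw.items():
        path = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
        if not path.exists():
            raise ConfigError(f"{key}.{name}: file not found: {path}")
        out[str(name)] = path
    return out


def _as_path(raw, base: Path, key: str, required: bool = False) -> Path | None:
    if raw is None:
        if required:
            raise ConfigError(f"{key}: required path missing")
        return None
    path = (base / raw).resolve() if not Path(raw).is_absolute() else Path(raw)
    if not path.exists():
        raise ConfigError(f"{key}: file not found: {path}")
    return path


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, default-fill and validate a YAML config file.

    Relative paths are resolved against the config file's directory; the
    full effective configuration is echoed to the log.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    params = dict(_PARAM_DEFAULTS)
    for key, value in (raw.get("params") or {}).items():
        if key not in _PARAM_DEFAULTS:
            raise ConfigError(f"params.{key}: unknown parameter")
        params[key] = value
    for key, (lo, hi) in _PARAM_RANGES.items():
        v = params[key]
        if not (lo <= v <= hi):
            raise ConfigError(f"params.{key}: value {v} outside [{lo}, {hi}]")
    if not (0 < params["clip_lo"] < params["clip_hi"] < 1):
        raise ConfigError("params.clip_lo/clip_hi: need 0 < lo < hi < 1")
    if params["halfwidth"] * 2 >= params["window"]:
        raise ConfigError("params.halfwidth: central window must be smaller than the scan window")

    peaks = _as_path_map(raw.get("peaks"), base, "peaks")
    cell_types = raw.get("cell_types") or list(peaks.keys())
    config = PipelineConfig(
        outdir=Path(raw.get("outdir", "occushift_out")),
        genome_fasta=_as_path(raw.get("genome_fasta"), base, "genome_fasta"),
        peaks=peaks,
        coverage=_as_path_map(raw.get("coverage"), base, "coverage"),
        blacklist=_as_path(raw.get("blacklist"), base, "blacklist"),
        partners=_as_path_map(raw.get("partners"), base, "partners"),
        pwms=_as_path_map(raw.get("pwms"), base, "pwms"),
        epus=_as_path(raw.get("epus"), base, "epus"),
        tss=_as_path(raw.get("tss"), base, "tss"),
        expression=_as_path(raw.get("expression"), base, "expression"),
        states=_as_path_map(raw.get("states"), base, "states"),
        series_order=list(raw.get("series_order") or []),
        cell_types=list(cell_types),
        params=params,
        grouping_map=raw.get("grouping_map"),
        source=path,
    )
    if not config.outdir.is_absolute():
        config.outdir = (base / config.outdir).resolve()
    logger.info("effective config: %s", json.dumps(config.effective(), sort_keys=True))
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_filtered_peaks(config: PipelineConfig) -> dict[str, PeakSet]:
    blacklist = (
        read_bed(config.blacklist, "blacklist") if config.blacklist else PeakSet("blacklist", [])
    )
    out = {}
    for ct in config.cell_types:
        if ct not in config.peaks:
            raise ConfigError(f"peaks.{ct}: no peak file for declared cell type")
        out[ct] = subtract_blacklist(read_bed(config.peaks[ct], ct), blacklist)
    return out


def run(config: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the requested stages (plus their dependency closure).

    Outputs are written only for the requested stages; a provenance
    manifest with content hashes of every written file is emitted at the
    end.  Returns a report dict of stage summaries.
    """
    requested = list(stages) if stages else list(ALL_STAGES)
    for s in requested:
        if s not in ALL_STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    closure: list[str] = []

    def add(stage: str) -> None:
        for dep in _STAGE_DEPS[stage]:
            add(dep)
        if stage not in closure:
            closure.append(stage)

    for s in requested:
        add(s)
    ordered = [s for s in ALL_STAGES if s in closure]

    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"report": {}}
    written: list[Path] = []

    for stage in ordered:
        write = stage in requested
        logger.info("stage %s (write=%s)", stage, write)
        try:
            _STAGE_FUNCS[stage](config, ctx, outdir if write else None, written)
        except Exception as exc:  # halt downstream dependents
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.effective(),
        "stages": ordered,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)},
    }
    manifest_path = outdir / "provenance.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    ctx["report"]["provenance"] = manifest["outputs"]
    return ctx["report"]


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_atlas(config: PipelineConfig, ctx: dict, outdir: Path | None, written: list[Path]) -> None:
    peaks = _load_filtered_peaks(config)
    os_list = merge_union([peaks[ct] for ct in config.cell_types])
    ctx["peaks"] = peaks
    ctx["os_list"] = os_list

    matrix = None
    if config.coverage:
        coverage = {ct: atlas_mod.read_bedgraph(p) for ct, p in config.coverage.items()}
        matrix = atlas_mod.count_signal(os_list, coverage)
        ctx["matrix"] = matrix

    grouping = None
    if config.grouping_map:
        grouping = {frozenset(v): k for k, v in config.grouping_map.items()}
    sharing = atlas_mod.partition_by_sharing(
        os_list,
        grouping_map=grouping,
        cell_types=config.cell_types,
    )
    ctx["sharing"] = sharing
    ctx["report"]["atlas"] = {
        "n_os": len(os_list),
        "sharing_counts": sharing.value_counts().sort_index().to_dict(),
    }

    if outdir is not None:
        with open(outdir / "atlas.bed", "w") as fh:
            for os in os_list:
                fh.write(
                    f"{os.chrom}\t{os.interval.start}\t{os.interval.end}\t{os.os_id}"
                    f"\t{len(os.members)}\t.\n"
                )
        written.append(outdir / "atlas.bed")
        sharing.to_frame().to_csv(outdir / "sharing_groups.tsv", sep="\t")
        written.append(outdir / "sharing_groups.tsv")
        if matrix is not None:
            coords = pd.DataFrame(
                {
                    "chrom": [o.chrom for o in os_list],
                    "start": [o.interval.start for o in os_list],
                    "end": [o.interval.end for o in os_list],
                },
                index=matrix.cpm.index,
            )
            out = coords.join(matrix.cpm.add_suffix("_cpm")).join(
                matrix.normalized.add_suffix("_qnorm")
            )
            out.to_csv(outdir / "occupancy_matrix.tsv", sep="\t", index_label="os_id")
            written.append(outdir / "occupancy_matrix.tsv")


def _stage_cluster(config: PipelineConfig, ctx: dict, outdir: Path | None, written: list[Path]) -> None:
    matrix = ctx.get("matrix")
    if matrix is None:
        raise ConfigError("cluster stage requires coverage tracks")
    norm = matrix.normalized
    clipped = clustering_mod.clip_quantiles(
        norm, float(config.params["clip_lo"]), float(config.params["clip_hi"])
    )
    k = min(int(config.params["k"]), norm.shape[0])
    result = clustering_mod.kmeans_cluster(
        norm, k=k, seed=int(config.params["seed"]), n_restarts=int(config.params["n_restarts"])
    )
    dendro = clustering_mod.correlation_dendrogram(matrix.cpm)
    ctx["clusters"] = result
    ctx["report"]["cluster"] = {
        "k": result.k,
        "inertia": result.inertia,
        "dendrogram": dendro.newick,
    }
    if outdir is not None:
        pd.DataFrame({"os_id": list(norm.index), "cluster": result.labels}).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
        written.append(outdir / "clusters.tsv")
        (outdir / "dendrogram.nwk").write_text(dendro.newick + "\n")
        written.append(outdir / "dendrogram.nwk")
        clipped.to_csv(outdir / "heatmap_matrix.tsv", sep="\t", index_label="os_id")
        written.append(outdir / "heatmap_matrix.tsv")


def _stage_motifs(config: PipelineConfig, ctx: dict, outdir: Path | None, written: list[Path]) -> None:
    if not config.pwms or config.genome_fasta is None:
        ctx["report"]["motifs"] = {"skipped": "no PWMs or genome configured"}
        return
    genome = Genome.read_fasta(config.genome_fasta).as_strings()
    os_list = ctx["os_list"]
    window = int(config.params["window"])
    halfwidth = int(config.params["halfwidth"])
    radius = window // 2
    windows = motifs_mod.extract_windows(genome, os_list, radius=radius)
    blacklist = read_bed(config.blacklist).intervals if config.blacklist else []
    randoms = motifs_mod.random_segments(
        genome, n=len(os_list), length=window,
        seed=int(config.params["seed"]), blacklist=blacklist,
    )

    @dataclass
    class _RandWin:
        os_id: str
        chrom: str
        midpoint: int

    random_windows = motifs_mod.extract_windows(
        genome,
        [_RandWin(f"R{i:05d}", iv.chrom, iv.midpoint) for i, iv in enumerate(randoms)],
        radius=radius,
    )

    rows = []
    inst_rows = []
    for pid, path in sorted(config.pwms.items()):
        pwm = motifs_mod.read_pwm(path)
        pwm = motifs_mod.PWM(pid, pwm.probs, pwm.background, pwm.pseudocount)
        threshold = motifs_mod.score_threshold(pwm, p=float(config.params["motif_p"]))
        instances = motifs_mod.scan(windows, pwm, threshold)
        rand_instances = motifs_mod.scan(random_windows, pwm, threshold)
        enr = motifs_mod.central_enrichment(
            instances, len(windows), rand_instances, len(random_windows),
            halfwidth=halfwidth, window=window, pwm_id=pid,
        )
        rows.append(
            {
                "pwm_id": pid, "a": enr.quad.a, "b": enr.quad.b,
                "c": enr.quad.c, "d": enr.quad.d,
                "log2_or": enr.log2_odds_ratio, "epsilon": enr.epsilon_applied,
                "n_instances": len(instances),
            }
        )
        for m in instances:
            inst_rows.append(
                {"pwm_id": pid, "os_id": m.os_id, "offset": m.offset,
                 "strand": m.strand, "score": round(m.score, 4)}
            )
    enrichment = pd.DataFrame(rows)
    ctx["motif_enrichment"] = enrichment
    ctx["report"]["motifs"] = {
        r["pwm_id"]: round(r["log2_or"], 4) for r in rows
    }
    if outdir is not None:
        enrichment.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
        written.append(outdir / "motif_enrichment.tsv")
        pd.DataFrame(inst_rows).to_csv(outdir / "motif_instances.tsv", sep="\t", index=False)
        written.append(outdir / "motif_instances.tsv")


def _require_partner(config: PipelineConfig, name: str) -> Path:
    if name not in config.partners:
        raise ConfigError(f"partners.{name}: required for the co-occupancy stage")
    return config.partners[name]


def _stage_cooccupancy(config: PipelineConfig, ctx: dict, outdir: Path | None, written: list[Path]) -> None:
    blacklist = (
        read_bed(config.blacklist, "blacklist") if config.blacklist else PeakSet("blacklist", [])
    )

    def load(name: str, path: Path) -> PeakSet:
        return subtract_blacklist(read_bed(path, name), blacklist)

    tal1_g1e = load("TAL1_G1E", config.peaks["G1E"]) if "G1E" in config.peaks else PeakSet("TAL1_G1E", [])
    tal1_er4 = load("TAL1_ER4", config.peaks["ER4"]) if "ER4" in config.peaks else PeakSet("TAL1_ER4", [])
    gata1 = load("GATA1_ER4", _require_partner(config, "GATA1_ER4"))

    universe = merge_union([tal1_g1e, tal1_er4, gata1], id_prefix="U")
    partition = cooc_mod.venn_partition(universe, tal1_g1e, tal1_er4, gata1)
    ctx["universe"] = universe
    ctx["partition"] = partition

    report: dict = {"group_sizes": partition["group"].value_counts().sort_index().to_dict()}
    tal1_universe = [u for u, g in zip(universe, partition["group"]) if g not in ("gata1_only", "none")]
    if tal1_universe:
        report["gata1_overlap_fraction"] = cooc_mod.overlap_fraction(tal1_universe, gata1)

    switch = None
    if "GATA2_G1E" in config.partners:
        gata2 = load("GATA2_G1E", config.partners["GATA2_G1E"])
        switch = cooc_mod.classify_switch(universe, gata2, gata1)
        report["switch_counts"] = switch["label"].value_counts().sort_index().to_dict()
        ctx["switch"] = switch

    overlaps = {}
    for name, path in sorted(config.partners.items()):
        partner = load(name, path)
        overlaps[name] = {
            ps_name: cooc_mod.overlap_fraction(load(ps_name, p), partner)
            for ps_name, p in sorted(config.peaks.items())
        }
    report["overlap_fractions"] = overlaps
    ctx["report"]["cooccupancy"] = report

    if outdir is not None:
        out = partition.copy()
        if switch is not None:
            out = out.join(switch[["label"]].rename(columns={"label": "switch_label"}))
        out.to_csv(outdir / "response_partition.tsv", sep="\t", index_label="os_id")
        written.append(outdir / "response_partition.tsv")
        with open(outdir / "cooccupancy_summary.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        written.append(outdir / "cooccupancy_summary.json")


def _stage_targets(config: PipelineConfig, ctx: dict, outdir: Path | None, written: list[Path]) -> None:
    if config.tss is None:
        raise ConfigError("targets stage requires a TSS annotation")
    genes = targets_mod.load_genes(config.tss)
    os_list = ctx.get("universe") or ctx["os_list"]
    maps = {}
    if config.epus is not None:
        epus = targets_mod.load_epus(config.epus)
        maps["epu"] = targets_mod.assign_by_epu(os_list, epus, genes)
    maps["nearest"] = targets_mod.assign_nearest_tss(os_list, genes)
    ctx["target_maps"] = maps
    ctx["report"]["targets"] = {
        method: {
            "n_os": len(tm.targets),
            "n_flagged": len(tm.flags),
            "mean_targets": float(np.mean([len(g) for g in tm.targets.values()]))
            if tm.targets else 0.0,
        }
        for method, tm in maps.items()
    }
    if outdir is not None:
        frames = [tm.to_frame() for tm in maps.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "target_assignment.tsv", sep="\t", index=False
        )
        written.append(outdir / "target_assignment.tsv")


def _stage_response(config: PipelineConfig, ctx: dict, outdir: Path | None, written: list[Path]) -> None:
    if config.expression is None:
        raise ConfigError("response stage requires an expression table")
    if config.tss is None:
        raise ConfigError("response stage requires a TSS annotation")
    genes = targets_mod.load_genes(config.tss)
    universe = ctx["universe"]
    if config.epus is not None:
        tmap = targets_mod.assign_by_epu(universe, targets_mod.load_epus(config.epus), genes)
    else:
        tmap = targets_mod.assign_nearest_tss(universe, genes)
    table = expr_mod.classify_de(
        expr_mod.read_expression_table(config.expression),
        active_threshold=float(config.params["active_threshold"]),
        fdr=float(config.params["fdr"]),
    )
    labels = table.set_index("gene_id")["label"]
    fractions, excluded = expr_mod.os_response_fractions(tmap, labels)
    partition = ctx["partition"]["group"]
    partition = partition[~partition.isin(["none"])]
    summary = expr_mod.permutation_null(
        fractions, partition,
        n_perm=int(config.params["n_perm"]), seed=int(config.params["seed"]),
    )
    ctx["response_summary"] = summary
    frame = summary.summary_frame()
    ctx["report"]["response"] = {
        f"{row.group}:{row.direction}": {
            "true_pct": round(float(row.true_pct), 3),
            "background_pct": round(float(row.background_pct), 3),
            "mean_log2_ratio": round(float(row.mean_log2_ratio), 4),
            "p_value": round(float(row.p_value), 5),
        }
        for row in frame.itertuples()
    }
    ctx["report"]["response"]["n_os_excluded_no_targets"] = excluded
    if outdir is not None:
        frame.to_csv(outdir / "response_summary.tsv", sep="\t", index=False)
        written.append(outdir / "response_summary.tsv")
        quantiles = {
            group: {
                direction: [
                    float(np.quantile(summary.log2_ratios[group][:, di], q))
                    for q in (0.0, 0.25, 0.5, 0.75, 1.0)
                ]
                for di, direction in enumerate(expr_mod.DIRECTIONS)
            }
            for group in summary.true_means.index
        }
        with open(outdir / "response_quantiles.json", "w") as fh:
            json.dump(quantiles, fh, indent=1, sort_keys=True)
        written.append(outdir / "response_quantiles.json")


def _stage_states(config: PipelineConfig, ctx: dict, outdir: Path | None, written: list[Path]) -> None:
    if not config.states:
        ctx["report"]["states"] = {"skipped": "no segmentations configured"}
        return
    series = config.series_order or list(config.states.keys())
    if len(series) != 3:
        raise ConfigError("series_order: the fate series needs exactly 3 cell types")
    segs = [states_mod.load_segmentation(config.states[ct], ct) for ct in series]
    os_list = ctx["os_list"]
    progenitor = config.cell_types[0]  # e.g. HPC7
    hpc7_only = [o for o in os_list if o.members == frozenset([progenitor])]
    table, summary = states_mod.fate_categorize(hpc7_only, segs)
    ctx["fates"] = (table, summary)
    ctx["report"]["states"] = {
        "progenitor_only_os": len(hpc7_only),
        "fate_percent": {c: round(float(summary.loc[c, "percent"]), 2) for c in summary.index},
    }
    if outdir is not None:
        if len(table):
            table.to_csv(outdir / "chromatin_fates.tsv", sep="\t", index_label="os_id")
            written.append(outdir / "chromatin_fates.tsv")
        with open(outdir / "fate_summary.json", "w") as fh:
            json.dump(
                {c: {"count": int(summary.loc[c, "count"]),
                     "percent": float(summary.loc[c, "percent"])} for c in summary.index},
                fh, indent=1, sort_keys=True,
            )
        written.append(outdir / "fate_summary.json")


_STAGE_FUNCS = {
    "atlas": _stage_atlas,
    "cluster": _stage_cluster,
    "motifs": _stage_motifs,
    "cooccupancy": _stage_cooccupancy,
    "targets": _stage_targets,
    "response": _stage_response,
    "states": _stage_states,
}


# ---------------------------------------------------------------------------
# Demo: simulate a fixture and run everything on it
# ---------------------------------------------------------------------------

def config_for_bundle(bundle, outdir: Path, params: Mapping[str, float | int] | None = None) -> PipelineConfig:
    """Build a pipeline config pointing at an emitted fixture bundle."""
    p = dict(_PARAM_DEFAULTS)
    p.update(params or {})
    return PipelineConfig(
        outdir=Path(outdir),
        genome_fasta=bundle.genome_fasta,
        peaks=dict(bundle.peak_beds),
        coverage=dict(bundle.coverage_bedgraphs),
        blacklist=bundle.blacklist_bed,
        partners=dict(bundle.partner_beds),
        pwms=dict(bundle.pwm_files),
        epus=bundle.epu_bed,
        tss=bundle.tss_bed,
        expression=bundle.expression_tsv,
        states=dict(bundle.state_beds),
        series_order=list(bundle.config.state_cell_types),
        cell_types=list(bundle.config.cell_types),
        params=p,
    )


def demo(outdir: str | Path, seed: int = 0, fixture_config=None,
         params: Mapping[str, float | int] | None = None) -> dict:
    """Simulate the default fixture and run the full pipeline on it.

    Returns the run report (also written to ``outdir/report.json``).
    """
    import dataclasses as _dc

    from .simulate import FixtureConfig, generate_bundle

    outdir = Path(outdir)
    fc = fixture_config or FixtureConfig()
    fc = _dc.replace(fc, seed=seed)
    bundle = generate_bundle(fc, outdir / "fixture")
    run_params = {"seed": seed, "n_perm": 1000}
    run_params.update(params or {})
    config = config_for_bundle(bundle, outdir / "results", run_params)
    report = run(config)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
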