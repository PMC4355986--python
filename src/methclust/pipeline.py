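"""End-to-end orchestration of the analysis stages with a manifest.

Stages run in a fixed order (simulate -> quantify -> dmr -> survival ->
features -> expression); each stage validates its inputs before any
compute, writes plain-text outputs into the working directory, and
appends a manifest entry recording parameters, input hashes and
runtime. A single seed feeds all stochastic stages through named
derived streams, so reruns with an identical config are file-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import expression as expr_mod
from . import features as feat_mod
from . import survival as surv_mod
from .io_formats import (
    read_gene_table,
    read_intervals,
    read_sample_sheet,
    write_dmr_output,
)
from .quantify import quantify_sample, write_track_bedgraph
from .synthetic import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "dmr", "survival", "features", "expression")


class PipelineError(RuntimeError):
    """A stage failed or its inputs were missing."""


@dataclass
class PipelineConfig:
    """All paths, toggles and thresholds of one pipeline run.

    With ``simulate`` enabled the cohort inputs default to the files the
    simulate stage writes under ``workdir/cohort``; otherwise the
    explicit paths must point at user-supplied files.
    """

    workdir: str
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    simulation: Dict = field(default_factory=dict)  # SimulationConfig overrides
    # dmr thresholds
    p_promoter: float = 0.05
    p_other: float = 0.01
    segmentation: str = "thirds"
    welch: bool = False
    # survival
    n_boot: int = 200
    cutoff_override: Optional[int] = None
    selection_p: float = 0.3
    # expression
    trim_fraction: float = 0.05
    # explicit input paths (defaults derived from workdir/cohort)
    genes_path: Optional[str] = None
    cgis_path: Optional[str] = None
    samples_path: Optional[str] = None
    reads_dir: Optional[str] = None
    chrom_sizes_path: Optional[str] = None
    genome_path: Optional[str] = None
    meth_matrix_path: Optional[str] = None
    expression_path: Optional[str] = None
    conservation_path: Optional[str] = None
    mask_path: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    # derived default locations
    def _cohort(self, name: str) -> Path:
        return Path(self.workdir) / "cohort" / name

    def path(self, key: str) -> Path:
        explicit = getattr(self, f"{key}_path", None)
        if explicit:
            return Path(explicit)
        defaults = {
            "genes": "genes.tsv", "cgis": "cgis.bed", "samples": "samples.tsv",
            "chrom_sizes": "chrom_sizes.tsv", "genome": "genome.fa",
            "meth_matrix": "meth_matrix.tsv", "expression": "expression.tsv",
            "conservation": "conservation.bedgraph",
        }
        return self._cohort(defaults[key])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_chrom_sizes(path: Path) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, length = line.split("\t")
        out[chrom] = int(length)
    return out


def _require(cfg: PipelineConfig, stage: str, paths: Dict[str, Path]) -> None:
    missing = [f"{k} ({v})" for k, v in paths.items() if not v.exists()]
    if missing:
        raise PipelineError(f"stage {stage}: missing inputs: {', '.join(missing)}")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the enabled stages in order; returns the manifest."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"config": dataclasses.asdict(config), "stages": []}
    enabled = [s for s in STAGES if s in config.stages]
    for stage in enabled:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        try:
            entry = _STAGE_FUNCS[stage](config, workdir)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        entry["stage"] = stage
        entry["runtime_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(entry)
        logger.info("stage %s: done in %.2fs", stage, entry["runtime_s"])
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_simulate(config: PipelineConfig, workdir: Path) -> Dict:
    sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
    cohort = simulate_cohort(sim)
    paths = write_cohort(cohort, workdir / "cohort")
    # conservation track for the features stage
    from .synthetic import simulate_conservation_track

    track = simulate_conservation_track(sim, cohort.annotation)
    cons_path = workdir / "cohort" / "conservation.bedgraph"
    with open(cons_path, "w") as fh:
        for iv in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")
    paths["conservation"] = str(cons_path)
    return {"params": dataclasses.asdict(sim), "outputs": paths}


def _stage_quantify(config: PipelineConfig, workdir: Path) -> Dict:
    reads_dir = Path(config.reads_dir) if config.reads_dir else workdir / "cohort" / "reads"
    chrom_sizes = config.path("chrom_sizes")
    _require(config, "quantify", {"reads_dir": reads_dir, "chrom_sizes": chrom_sizes})
    chrom_lengths = _read_chrom_sizes(chrom_sizes)
    mask = None
    if config.mask_path:
        mask = read_intervals(config.mask_path, dialect="bed")
    tracks_dir = workdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    inputs = {}
    lib_sizes = []
    for bed in sorted(reads_dir.glob("*.bed")):
        sample_id = bed.stem
        reads = read_intervals(bed, dialect="bed")
        track = quantify_sample(reads, chrom_lengths, sample_id=sample_id,
                                exclusion_mask=mask)
        write_track_bedgraph(track, tracks_dir / f"{sample_id}.bedgraph")
        lib_sizes.append((sample_id, track.n_unique_reads, track.norm_factor))
        inputs[str(bed)] = _sha256(bed)
    if not lib_sizes:
        raise PipelineError(f"stage quantify: no .bed files in {reads_dir}")
    pd.DataFrame(lib_sizes, columns=["sample_id", "n_unique_reads", "norm_factor"]).to_csv(
        tracks_dir / "library_sizes.tsv", sep="\t", index=False
    )
    return {"inputs": inputs, "outputs": {"tracks_dir": str(tracks_dir)}}


def _load_tracks(config: PipelineConfig, workdir: Path):
    from .quantify import read_track_bedgraph

    tracks_dir = workdir / "tracks"
    lib = pd.read_csv(tracks_dir / "library_sizes.tsv", sep="\t")
    chrom_lengths = _read_chrom_sizes(config.path("chrom_sizes"))
    tracks = {}
    for _, row in lib.iterrows():
        tracks[row["sample_id"]] = read_track_bedgraph(
            tracks_dir / f"{row['sample_id']}.bedgraph",
            chrom_lengths, int(row["n_unique_reads"]), sample_id=row["sample_id"],
        )
    return tracks, chrom_lengths


def _stage_dmr(config: PipelineConfig, workdir: Path) -> Dict:
    genes_p, cgis_p, samples_p = (
        config.path("genes"), config.path("cgis"), config.path("samples"),
    )
    _require(config, "dmr", {"genes": genes_p, "cgis": cgis_p, "samples": samples_p,
                             "tracks": workdir / "tracks" / "library_sizes.tsv"})
    genes = read_gene_table(genes_p)
    cgis = read_intervals(cgis_p, dialect="bed")
    samples = read_sample_sheet(samples_p)
    tracks, chrom_lengths = _load_tracks(config, workdir)
    tumor = [tracks[s.sample_id] for s in samples
             if s.group == "tumor" and s.sample_id in tracks]
    normal = [tracks[s.sample_id] for s in samples
              if s.group == "normal" and s.sample_id in tracks]
    regions = dmr_mod.classify_regions(genes, cgis)
    thresholds = {
        dmr_mod.PROMOTER_CGI: config.p_promoter,
        dmr_mod.INTRAGENIC_CGI: config.p_other,
        dmr_mod.INTERGENIC_CGI: config.p_other,
        dmr_mod.NONCGI_PROMOTER: config.p_other,
    }
    records = dmr_mod.call_dmrs(
        regions, tumor, normal, chrom_lengths,
        thresholds=thresholds, welch=config.welch,
        segmentation=config.segmentation,
    )
    out_dir = workdir / "dmrs"
    out_dir.mkdir(exist_ok=True)
    write_dmr_output(records, out_dir / "dmrs.bed", out_dir / "dmrs.tsv")
    summary = dmr_mod.summarize_fractions(records, regions)
    rows = [
        {"region_class": cls, **vals} for cls, vals in summary["classes"].items()
    ]
    pd.DataFrame(rows).to_csv(out_dir / "class_summary.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return {
        "inputs": {str(p): _sha256(p) for p in (genes_p, cgis_p, samples_p)},
        "params": {"thresholds": thresholds, "segmentation": config.segmentation},
        "outputs": {"dmr_dir": str(out_dir)},
        "n_records": len(records),
        "n_dmrs": int(sum(r.is_dmr for r in records)),
    }


def _stage_survival(config: PipelineConfig, workdir: Path) -> Dict:
    genes_p, samples_p, meth_p = (
        config.path("genes"), config.path("samples"), config.path("meth_matrix"),
    )
    _require(config, "survival", {"genes": genes_p, "samples": samples_p,
                                  "meth_matrix": meth_p})
    genes = read_gene_table(genes_p)
    samples = read_sample_sheet(samples_p)
    meth = pd.read_csv(meth_p, sep="\t", index_col=0)
    tumors = [s for s in samples
              if s.group == "tumor" and s.os_time is not None and s.sample_id in meth.index]
    ids = [s.sample_id for s in tumors]
    times = pd.Series([s.os_time for s in tumors], index=ids)
    events = pd.Series([s.os_event for s in tumors], index=ids)
    meth_t = meth.loc[ids]

    clusters: Dict[str, List[str]] = {}
    for g in genes:
        if g.cluster_id:
            clusters.setdefault(g.cluster_id, []).append(g.gene_id)

    out_dir = workdir / "survival"
    out_dir.mkdir(exist_ok=True)
    cluster_rows, km_rows, cox_rows = [], [], []
    for cid, cluster_genes in sorted(clusters.items()):
        try:
            strat = surv_mod.analyze_cluster(
                meth_t, cluster_genes, times, events, cluster_id=cid,
                n_boot=config.n_boot, seed=config.seed,
                cutoff_override=config.cutoff_override,
                selection_p=config.selection_p,
            )
        except surv_mod.UnevaluableCluster as exc:
            cluster_rows.append({"cluster_id": cid, "evaluable": 0,
                                 "note": str(exc)})
            continue
        cluster_rows.append({
            "cluster_id": cid, "evaluable": 1,
            "n_selected_genes": len(strat.selected_genes),
            "selected_genes": ",".join(strat.selected_genes),
            "cutoff": strat.cutoff,
            "n_high": int(strat.group_high.sum()),
            "n_low": int((~strat.group_high).sum()),
            "logrank_stat": strat.logrank_stat,
            "logrank_p": strat.logrank_p,
            "note": "",
        })
        for label, curve in strat.km_curves.items():
            for _, row in curve.iterrows():
                km_rows.append({"cluster_id": cid, "group": label,
                                "time": row["time"], "survival": row["survival"]})
        cox = surv_mod.cox_fit(
            group=strat.group_high.astype(int).to_numpy(),
            times=times.to_numpy(), events=events.to_numpy(),
            age=[s.age for s in tumors], grade=[s.grade for s in tumors],
            er_status=[s.er_status for s in tumors],
        )
        if cox.converged:
            for cov, row in cox.table.iterrows():
                cox_rows.append({"cluster_id": cid, "covariate": cov, **row.to_dict()})
    pd.DataFrame(cluster_rows).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(km_rows).to_csv(out_dir / "km_curves.tsv", sep="\t", index=False)
    pd.DataFrame(cox_rows).to_csv(out_dir / "cox.tsv", sep="\t", index=False)
    return {
        "inputs": {str(p): _sha256(p) for p in (genes_p, samples_p, meth_p)},
        "params": {"n_boot": config.n_boot, "cutoff_override": config.cutoff_override,
                   "selection_p": config.selection_p, "seed": config.seed},
        "outputs": {"survival_dir": str(out_dir)},
        "n_clusters": len(clusters),
    }


def _stage_features(config: PipelineConfig, workdir: Path) -> Dict:
    genes_p, genome_p = config.path("genes"), config.path("genome")
    _require(config, "features", {"genes": genes_p, "genome": genome_p})
    import pyfaidx

    genes = read_gene_table(genes_p)
    genome = pyfaidx.Fasta(str(genome_p))
    gc = feat_mod.profile_matrix(genes, genome=genome)
    out_dir = workdir / "features"
    out_dir.mkdir(exist_ok=True)
    clusters: Dict[str, List[str]] = {}
    for g in genes:
        if g.cluster_id:
            clusters.setdefault(g.cluster_id, []).append(g.gene_id)
    for cid, members in sorted(clusters.items()):
        summary = feat_mod.cluster_profile_summary(gc, members)
        summary.to_frame().to_csv(out_dir / f"gc_profile_{cid}.tsv",
                                  sep="\t", index=False)
    cons_p = config.path("conservation")
    if cons_p.exists():
        track = read_intervals(cons_p, dialect="bedgraph")
        chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
        cons = feat_mod.profile_matrix(genes, conservation_track=track,
                                       chrom_lengths=chrom_lengths)
        for cid, members in sorted(clusters.items()):
            summary = feat_mod.cluster_profile_summary(cons, members)
            summary.to_frame().to_csv(out_dir / f"conservation_profile_{cid}.tsv",
                                      sep="\t", index=False)
    return {
        "inputs": {str(genes_p): _sha256(genes_p)},
        "outputs": {"features_dir": str(out_dir)},
        "n_profiled_genes": int(len(gc)),
    }


def _stage_expression(config: PipelineConfig, workdir: Path) -> Dict:
    expr_p, samples_p, meth_p = (
        config.path("expression"), config.path("samples"), config.path("meth_matrix"),
    )
    _require(config, "expression", {"expression": expr_p, "samples": samples_p,
                                    "meth_matrix": meth_p})
    expr = pd.read_csv(expr_p, sep="\t", index_col=0)
    meth = pd.read_csv(meth_p, sep="\t", index_col=0)
    samples = read_sample_sheet(samples_p)
    out_dir = workdir / "expression"
    out_dir.mkdir(exist_ok=True)
    z, constant = expr_mod.zscore_log_expression(expr)
    z.to_csv(out_dir / "zscore.tsv", sep="\t", index_label="gene_id")
    normals = [s.sample_id for s in samples if s.group == "normal"]
    tumors = [s.sample_id for s in samples if s.group == "tumor"]
    fc_rows = {}
    if normals and tumors:
        fc_rows["tumor_vs_normal"] = expr_mod.group_log2_fc(expr, normals, tumors)
    er_pos = [s.sample_id for s in samples if s.er_status == "positive"]
    er_neg = [s.sample_id for s in samples if s.er_status == "negative"]
    if er_pos and er_neg:
        fc_rows["er_pos_vs_er_neg"] = expr_mod.group_log2_fc(expr, er_neg, er_pos)
    if fc_rows:
        pd.DataFrame(fc_rows).to_csv(out_dir / "fc.tsv", sep="\t",
                                     index_label="gene_id")
    corr = expr_mod.correlation_table(meth, expr, trim_fraction=config.trim_fraction)
    corr.to_csv(out_dir / "correlation.tsv", sep="\t")
    return {
        "inputs": {str(p): _sha256(p) for p in (expr_p, samples_p, meth_p)},
        "params": {"trim_fraction": config.trim_fraction},
        "outputs": {"expression_dir": str(out_dir)},
        "n_constant_genes": int(constant.sum()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "dmr": _stage_dmr,
    "survival": _stage_survival,
    "features": _stage_features,
    "expression": _stage_expression,
}
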