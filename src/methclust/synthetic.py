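"""Synthetic MBD-seq study generator with machine-readable ground truth.

Emulates the statistical structure of a tumor/normal methyl-capture
cohort at desk scale: a random genome laid out in fixed slots hosting
genes (grouped into clusters of consecutive genes on one chromosome)
and CpG islands; per-sample reads whose 100-bp bin counts are Poisson
with tumor-specific rate elevation over planted hypermethylated
windows; a clinical table whose hazard depends on a planted high-risk
patient group through an exponential proportional-hazards model; a
promoter methylation matrix separating high- and low-risk patients at
one risk cluster; and an RPKM expression matrix negatively coupled to
promoter methylation.

Two deliberately separate layers share one config:

* the **read layer** plants window-level tumor-vs-normal rate effects
  (all tumors elevated) and is the ground truth for DMR calling;
* the **survival/expression layer** generates per-patient per-gene
  promoter methylation directly, with the planted patient risk group
  elevated at the risk cluster's genes, and is the ground truth for
  stratification and methylation-expression coupling.

Keeping the layers separate means each analysis is evaluated against
an uncontaminated truth (patient-subgroup effects do not leak into the
group-level DMR screen and vice versa).

All outputs are pure functions of (config, seed): the same config
yields byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    GeneModel,
    GenomicInterval,
    SampleRecord,
    write_gene_table,
    write_intervals,
    write_sample_sheet,
)

SLOT_BP = 24_000  # per-entity pitch; keeps 8-kb analysis windows disjoint
TSS_OFFSET_PLUS = 6_000  # TSS position within a slot for + strand genes
TSS_OFFSET_MINUS = 18_000  # for - strand genes (body extends genomically left)
GENE_BODY_BP = 12_000
INTRAGENIC_CGI_OFFSET = 8_800  # downstream of TSS; keeps window centers >= 8 kb apart
WINDOW_HALF = 4_000

# named RNG streams: one seed, independent per-stage draws
_STREAMS = {
    "genome": 1, "annotation": 2, "planting": 3, "reads": 4,
    "clinical": 5, "methylation": 6, "expression": 7,
}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream], extra))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror a scaled-down two-group methyl-capture study: 20
    tumors vs 10 normals, 200 analysis windows on one chromosome of
    which 15% carry a planted 3x tumor rate elevation, and a planted
    patient risk group with a hazard ratio of 2.

    ``background_slots`` appends window-free background genome so that
    analysis windows cover ~7% of the genome, the share CGI/promoter
    windows occupy in a mammalian genome. This matters statistically:
    enrichment sequencing is compositional, so planted signal inflates
    a tumor library's total read count and, through the library-size
    normalization, systematically deflates every null bin. With a
    realistic background share that distortion is negligible; without
    it the null calibration of the group comparison breaks down.
    """

    seed: int = 0
    n_chroms: int = 1
    n_genes: int = 120
    n_clusters: int = 4
    genes_per_cluster: int = 9
    p_cgi: float = 0.7  # probability a gene promoter carries a CGI
    n_intragenic_cgis: int = 46
    n_intergenic_cgis: int = 34
    background_slots: int = 800  # window-free 24-kb slots of background genome
    cgi_length_bp: int = 800
    gc_content: float = 0.45
    n_tumor: int = 20
    n_normal: int = 10
    baseline_bin_rate: float = 0.5  # expected reads per 100-bp bin
    mean_reads_per_sample: Optional[int] = None  # derived when None
    read_length: int = 36
    planted_dmr_fraction: float = 0.15
    dmr_effect: float = 3.0  # tumor/normal rate ratio over planted windows
    true_log_hr: float = math.log(2.0)
    baseline_hazard: float = 0.1  # events per time unit
    censoring_fraction: float = 0.2
    high_risk_fraction: float = 0.25  # planted high-methylation patient share
    beta_age: float = 0.02  # nuisance log-hazard per year (centered at 58)
    beta_grade: float = 0.2  # nuisance log-hazard per grade step (centered at 2)
    base_promoter_meth: float = 5.0  # normalized-count units
    meth_sd: float = 1.0
    risk_meth_shift: float = 4.0  # elevation of risk-cluster genes in high-risk patients
    expr_coupling_gamma: float = 1.0  # log-expression decay per methylation unit
    noise_sd: float = 0.75  # lognormal expression noise (natural-log sd)
    bin_size: int = 100

    def __post_init__(self) -> None:
        for name in ("n_chroms", "n_genes", "n_clusters", "genes_per_cluster",
                     "n_tumor", "n_normal", "cgi_length_bp", "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dmr_effect < 1:
            raise ValueError("dmr_effect must be >= 1")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.n_clusters * self.genes_per_cluster > self.n_genes:
            raise ValueError("more clustered genes than genes")

    @property
    def n_windows(self) -> int:
        return self.n_genes + self.n_intragenic_cgis + self.n_intergenic_cgis

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class PlantedRegion:
    """A window carrying a true tumor-vs-normal rate difference."""

    interval: GenomicInterval
    normal_rate: float
    tumor_rate: float
    direction: str = "hyper"


@dataclass
class GroundTruth:
    """Everything the evaluator needs: planted effects and true parameters."""

    planted_regions: List[PlantedRegion] = field(default_factory=list)
    window_centers: List[tuple] = field(default_factory=list)  # (chrom, center, class)
    cluster_true_log_hr: Dict[str, float] = field(default_factory=dict)
    risk_cluster: Optional[str] = None
    patient_risk_group: Dict[str, int] = field(default_factory=dict)
    gene_meth_rates: Dict[str, Dict[str, float]] = field(default_factory=dict)
    expr_coupling: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_regions": [
                {
                    "chrom": p.interval.chrom,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "normal_rate": p.normal_rate,
                    "tumor_rate": p.tumor_rate,
                    "direction": p.direction,
                }
                for p in self.planted_regions
            ],
            "window_centers": self.window_centers,
            "cluster_true_log_hr": self.cluster_true_log_hr,
            "risk_cluster": self.risk_cluster,
            "patient_risk_group": self.patient_risk_group,
            "gene_meth_rates": self.gene_meth_rates,
            "expr_coupling": self.expr_coupling,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class Annotation:
    """In-memory result of simulate_annotation."""

    genome: Dict[str, str]
    genes: List[GeneModel]
    cgis: List[GenomicInterval]
    chrom_lengths: Dict[str, int]
    truth: GroundTruth


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return codes.tobytes().decode("ascii")


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Lay out genome, genes, clusters and CGIs, and plant DMR windows.

    Entities (genes and intergenic CGIs) occupy disjoint 24-kb slots so
    that no two 8-kb analysis windows overlap; clustered genes occupy
    consecutive slots of one chromosome. Each gene promoter carries a
    CGI with probability ``p_cgi``; the first ``n_intragenic_cgis``
    genes additionally host an intragenic CGI 8.8 kb into the gene
    body. A ``planted_dmr_fraction`` share of all windows is selected
    for a ``dmr_effect``-fold tumor rate elevation spanning the whole
    window.
    """
    rng_ann = _rng(config.seed, "annotation")
    if config.n_intragenic_cgis > config.n_genes:
        raise ValueError("cannot host more intragenic CGIs than genes")

    n_slots_total = config.n_genes + config.n_intergenic_cgis
    # slack lets whole clusters bump to the next chromosome intact
    slack = config.genes_per_cluster if config.n_chroms > 1 else 0
    slots_per_chrom = math.ceil(n_slots_total / config.n_chroms) + slack

    # entity order: clustered genes first (consecutive), then loose
    # genes, then intergenic CGI slots; chromosomes fill sequentially
    # but a cluster is bumped to the next chromosome rather than split.
    entity_plan: List[tuple] = []
    gene_idx = 0
    for k in range(config.n_clusters):
        entity_plan.extend(
            ("gene", gene_idx + i, f"cluster_{k + 1}")
            for i in range(config.genes_per_cluster)
        )
        gene_idx += config.genes_per_cluster
    while gene_idx < config.n_genes:
        entity_plan.append(("gene", gene_idx, None))
        gene_idx += 1
    entity_plan.extend(("icgi", j, None) for j in range(config.n_intergenic_cgis))

    chrom_names = [f"chr{c + 1}" for c in range(config.n_chroms)]
    placements: List[tuple] = []  # (kind, index, cluster, chrom, slot_start)
    used_slots = {c: 0 for c in chrom_names}
    chrom_cursor, slot_cursor = 0, 0
    i = 0
    while i < len(entity_plan):
        kind, idx, cluster = entity_plan[i]
        size = config.genes_per_cluster if cluster is not None else 1
        if slot_cursor + size > slots_per_chrom:
            chrom_cursor += 1
            slot_cursor = 0
        if chrom_cursor >= len(chrom_names) or size > slots_per_chrom:
            raise ValueError("genome too small to place all entities without "
                             "splitting a cluster across chromosomes")
        for j in range(size):
            placements.append(
                entity_plan[i + j][:3]
                + (chrom_names[chrom_cursor], slot_cursor * SLOT_BP)
            )
            slot_cursor += 1
        used_slots[chrom_names[chrom_cursor]] = slot_cursor
        i += size

    chrom_lengths = {
        c: n * SLOT_BP for c, n in used_slots.items() if n > 0
    }
    # window-free background sequence, appended to the last chromosome
    if config.background_slots > 0:
        last = list(chrom_lengths)[-1]
        chrom_lengths[last] += config.background_slots * SLOT_BP

    genes: List[GeneModel] = []
    cgis: List[GenomicInterval] = []
    truth = GroundTruth()
    half_cgi = config.cgi_length_bp // 2
    n_genes_seen = 0
    for kind, idx, cluster, chrom, slot_start in placements:
        if kind == "gene":
            strand = "+" if rng_ann.random() < 0.5 else "-"
            if strand == "+":
                tss = slot_start + TSS_OFFSET_PLUS
                g = GeneModel(f"gene_{idx:04d}", chrom, "+", tss, tss,
                              tss + GENE_BODY_BP, cluster)
                intragenic_center = tss + INTRAGENIC_CGI_OFFSET
            else:
                tss = slot_start + TSS_OFFSET_MINUS
                g = GeneModel(f"gene_{idx:04d}", chrom, "-", tss,
                              tss - GENE_BODY_BP, tss, cluster)
                intragenic_center = tss - INTRAGENIC_CGI_OFFSET
            genes.append(g)
            has_cgi = rng_ann.random() < config.p_cgi
            if has_cgi:
                cgis.append(GenomicInterval(chrom, tss - half_cgi, tss + half_cgi))
            if n_genes_seen < config.n_intragenic_cgis:
                cgis.append(
                    GenomicInterval(chrom, intragenic_center - half_cgi,
                                    intragenic_center + half_cgi)
                )
                truth.window_centers.append((chrom, int(intragenic_center),
                                             "intragenic_CGI"))
            truth.window_centers.append(
                (chrom, int(tss), "promoter_CGI" if has_cgi else "nonCGI_promoter")
            )
            n_genes_seen += 1
        else:
            center = slot_start + TSS_OFFSET_PLUS
            cgis.append(GenomicInterval(chrom, center - half_cgi, center + half_cgi))
            truth.window_centers.append((chrom, int(center), "intergenic_CGI"))

    rng_gen = _rng(config.seed, "genome")
    genome = {
        chrom: _random_sequence(rng_gen, length, config.gc_content)
        for chrom, length in chrom_lengths.items()
    }

    # plant DMR windows
    rng_plant = _rng(config.seed, "planting")
    n_planted = int(round(config.planted_dmr_fraction * len(truth.window_centers)))
    order = rng_plant.permutation(len(truth.window_centers))
    for pos in order[:n_planted]:
        chrom, center, _cls = truth.window_centers[pos]
        iv = GenomicInterval(chrom, center - WINDOW_HALF, center + WINDOW_HALF)
        truth.planted_regions.append(
            PlantedRegion(
                interval=iv,
                normal_rate=config.baseline_bin_rate,
                tumor_rate=config.baseline_bin_rate * config.dmr_effect,
            )
        )

    # survival truth: first cluster is the risk cluster
    for k in range(config.n_clusters):
        cid = f"cluster_{k + 1}"
        truth.cluster_true_log_hr[cid] = config.true_log_hr if k == 0 else 0.0
    truth.risk_cluster = "cluster_1"
    truth.expr_coupling = {
        "gamma": config.expr_coupling_gamma,
        "noise_sd": config.noise_sd,
    }
    risk_genes = {g.gene_id for g in genes if g.cluster_id == truth.risk_cluster}
    for g in genes:
        base = config.base_promoter_meth
        shift = config.risk_meth_shift if g.gene_id in risk_genes else 0.0
        truth.gene_meth_rates[g.gene_id] = {
            "low_risk_mean": base,
            "high_risk_mean": base + shift,
            "normal_mean": base - 1.0,
        }
    return Annotation(genome=genome, genes=genes, cgis=cgis,
                      chrom_lengths=chrom_lengths, truth=truth)


def _bin_rates(
    config: SimulationConfig,
    truth: GroundTruth,
    chrom_lengths: Dict[str, int],
    is_tumor: bool,
) -> Dict[str, np.ndarray]:
    rates = {
        chrom: np.full((length + config.bin_size - 1) // config.bin_size,
                       config.baseline_bin_rate)
        for chrom, length in chrom_lengths.items()
    }
    if is_tumor:
        for planted in truth.planted_regions:
            iv = planted.interval
            first = iv.start // config.bin_size
            last = (iv.end - 1) // config.bin_size + 1
            rates[iv.chrom][first:last] = planted.tumor_rate
    return rates


def simulate_reads(
    config: SimulationConfig,
    truth: GroundTruth,
    sample: SampleRecord,
    chrom_lengths: Dict[str, int],
    sample_index: int = 0,
) -> List[GenomicInterval]:
    """Draw one sample's aligned reads.

    Per-bin read counts are Poisson with rate ``baseline_bin_rate``,
    multiplied by ``dmr_effect`` over planted windows for tumor samples
    only; each read starts uniformly within its bin and spans
    ``read_length`` bases (clipped at the chromosome end).
    """
    rng = _rng(config.seed, "reads", extra=sample_index)
    rates = _bin_rates(config, truth, chrom_lengths, sample.group == "tumor")
    reads: List[GenomicInterval] = []
    for chrom, rate_vec in rates.items():
        counts = rng.poisson(rate_vec)
        bin_idx = np.repeat(np.arange(len(rate_vec)), counts)
        offsets = rng.integers(0, config.bin_size, size=len(bin_idx))
        starts = bin_idx * config.bin_size + offsets
        ends = np.minimum(starts + config.read_length, chrom_lengths[chrom])
        starts = np.minimum(starts, chrom_lengths[chrom] - 1)
        for s, e in zip(starts.tolist(), ends.tolist()):
            reads.append(GenomicInterval(chrom, s, max(e, s + 1)))
    return reads


def expected_reads_per_sample(config: SimulationConfig,
                              chrom_lengths: Dict[str, int],
                              truth: GroundTruth, tumor: bool = False) -> float:
    rates = _bin_rates(config, truth, chrom_lengths, tumor)
    return float(sum(v.sum() for v in rates.values()))


def simulate_clinical(
    config: SimulationConfig,
    truth: GroundTruth,
    n_tumor: Optional[int] = None,
) -> List[SampleRecord]:
    """Draw the clinical table: covariates, risk group, survival.

    Event times follow an exponential proportional-hazards model

        h_i = baseline_hazard * exp(log_hr * risk_i
                                    + beta_age * (age_i - 58)
                                    + beta_grade * (grade_i - 2))

    with independent uniform censoring on (0, u); u is solved so the
    expected censored share equals ``censoring_fraction``. Normal
    samples carry no clinical covariates.
    """
    rng = _rng(config.seed, "clinical")
    n_tumor = config.n_tumor if n_tumor is None else int(n_tumor)
    ages = np.clip(rng.normal(58.0, 10.0, size=n_tumor), 30.0, 90.0)
    grades = rng.choice([1, 2, 3], p=[0.2, 0.5, 0.3], size=n_tumor)
    er = rng.choice(["positive", "negative"], p=[2 / 3, 1 / 3], size=n_tumor)
    risk = (rng.random(n_tumor) < config.high_risk_fraction).astype(int)
    log_hr = truth.cluster_true_log_hr.get(truth.risk_cluster or "", 0.0)
    hazards = config.baseline_hazard * np.exp(
        log_hr * risk
        + config.beta_age * (ages - 58.0)
        + config.beta_grade * (grades - 2.0)
    )
    times = rng.exponential(1.0 / hazards)

    if config.censoring_fraction > 0:
        def expected_censored(u: float) -> float:
            lu = hazards * u
            return float(np.mean((1.0 - np.exp(-lu)) / lu)) - config.censoring_fraction

        # E[P(C<T)] decreases from 1 (u->0) to 0 (u->inf); bracket widely
        u = brentq(expected_censored, 1e-9 / config.baseline_hazard,
                   1e6 / config.baseline_hazard)
        censor_times = rng.uniform(0.0, u, size=n_tumor)
        observed = np.minimum(times, censor_times)
        events = (times <= censor_times).astype(int)
    else:
        observed, events = times, np.ones(n_tumor, dtype=int)

    records: List[SampleRecord] = []
    for i in range(n_tumor):
        sid = f"tumor_{i + 1:03d}"
        truth.patient_risk_group[sid] = int(risk[i])
        records.append(
            SampleRecord(
                sample_id=sid, group="tumor", er_status=str(er[i]),
                age=float(round(ages[i], 1)), grade=int(grades[i]),
                os_time=float(max(observed[i], 1e-6)), os_event=int(events[i]),
            )
        )
    for j in range(config.n_normal):
        records.append(SampleRecord(sample_id=f"normal_{j + 1:03d}", group="normal"))
    return records


def simulate_methylation_matrix(
    config: SimulationConfig,
    truth: GroundTruth,
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Per-patient per-gene promoter methylation (patients x genes).

    Values are normal around the true group mean recorded in the ground
    truth (risk-cluster genes elevated for high-risk patients), with sd
    ``meth_sd``, floored at zero.
    """
    rng = _rng(config.seed, "methylation")
    rows = {}
    for s in samples:
        vals = []
        for g in genes:
            r = truth.gene_meth_rates[g.gene_id]
            if s.group == "normal":
                mu = r["normal_mean"]
            elif truth.patient_risk_group.get(s.sample_id, 0) == 1:
                mu = r["high_risk_mean"]
            else:
                mu = r["low_risk_mean"]
            vals.append(mu)
        rows[s.sample_id] = np.asarray(vals)
    ids = list(rows)
    noise = rng.normal(0.0, config.meth_sd, size=(len(ids), len(genes)))
    mat = np.maximum(np.vstack([rows[i] for i in ids]) + noise, 0.0)
    return pd.DataFrame(mat, index=ids, columns=[g.gene_id for g in genes])


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    meth: pd.DataFrame,
) -> pd.DataFrame:
    """RPKM expression (genes x samples) negatively coupled to methylation.

    expr[g, s] = base_g * exp(-gamma * (meth[s, g] - mean_g)) * lognormal
    noise; with gamma > 0 this induces a negative correlation between
    promoter methylation and log expression.
    """
    rng = _rng(config.seed, "expression")
    gamma = config.expr_coupling_gamma
    base = rng.lognormal(mean=math.log(20.0), sigma=0.5, size=meth.shape[1])
    centered = meth.to_numpy() - meth.to_numpy().mean(axis=0, keepdims=True)
    noise = rng.normal(0.0, config.noise_sd, size=meth.shape)
    expr = base[None, :] * np.exp(-gamma * centered + noise)
    return pd.DataFrame(expr.T, index=meth.columns, columns=meth.index)


def simulate_conservation_track(
    config: SimulationConfig, annotation: Annotation, step: int = 50
) -> List[GenomicInterval]:
    """Synthetic per-base conservation scores as a 50-bp step bedGraph.

    Baseline noise is Beta(2, 5); a smooth exponential bump of height
    0.3 and 500-bp scale is added around every TSS so metagene profiles
    show the expected promoter-proximal structure. Values are clipped
    to [0, 1]. This is a synthetic stand-in shaped like a phastCons
    track, not derived from any alignment.
    """
    rng = _rng(config.seed, "genome", extra=1)
    tss_by_chrom: Dict[str, np.ndarray] = {}
    for g in annotation.genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in annotation.genes:
        tss_by_chrom[g.chrom].append(g.tss)
    track: List[GenomicInterval] = []
    for chrom, length in annotation.chrom_lengths.items():
        n_steps = length // step
        centers = (np.arange(n_steps) + 0.5) * step
        values = rng.beta(2.0, 5.0, size=n_steps)
        for tss in tss_by_chrom.get(chrom, ()):
            values += 0.3 * np.exp(-np.abs(centers - tss) / 500.0)
        values = np.clip(values, 0.0, 1.0)
        for i in range(n_steps):
            track.append(
                GenomicInterval(chrom, i * step, (i + 1) * step,
                                score=float(round(values[i], 4)))
            )
    return track


@dataclass
class Cohort:
    """A fully materialized synthetic study."""

    config: SimulationConfig
    annotation: Annotation
    samples: List[SampleRecord]
    reads: Dict[str, List[GenomicInterval]]
    methylation: pd.DataFrame
    expression: pd.DataFrame

    @property
    def truth(self) -> GroundTruth:
        return self.annotation.truth


def simulate_cohort(config: SimulationConfig, with_reads: bool = True) -> Cohort:
    """Generate the full study in memory (reads optional: they dominate cost)."""
    ann = simulate_annotation(config)
    samples = simulate_clinical(config, ann.truth)
    reads: Dict[str, List[GenomicInterval]] = {}
    if with_reads:
        for i, s in enumerate(samples):
            reads[s.sample_id] = simulate_reads(config, ann.truth, s,
                                                ann.chrom_lengths, sample_index=i)
    meth = simulate_methylation_matrix(config, ann.truth, samples, ann.genes)
    expr = simulate_expression(config, ann.truth, meth)
    return Cohort(config, ann, samples, reads, meth, expr)


def write_cohort(cohort: Cohort, outdir) -> Dict[str, str]:
    """Write every cohort artifact as plain text; returns a path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in cohort.annotation.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = str(fasta)

    write_gene_table(cohort.annotation.genes, outdir / "genes.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    write_intervals(cohort.annotation.cgis, outdir / "cgis.bed",
                    names=[f"cgi_{i}" for i in range(len(cohort.annotation.cgis))])
    paths["cgis"] = str(outdir / "cgis.bed")
    write_sample_sheet(cohort.samples, outdir / "samples.tsv")
    paths["samples"] = str(outdir / "samples.tsv")

    chrom_file = outdir / "chrom_sizes.tsv"
    with open(chrom_file, "w") as fh:
        for chrom, length in cohort.annotation.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["chrom_sizes"] = str(chrom_file)

    if cohort.reads:
        reads_dir = outdir / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sid, reads in cohort.reads.items():
            with open(reads_dir / f"{sid}.bed", "w") as fh:
                for r in reads:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
        paths["reads_dir"] = str(reads_dir)

    cohort.methylation.to_csv(outdir / "meth_matrix.tsv", sep="\t",
                              index_label="sample_id")
    paths["methylation"] = str(outdir / "meth_matrix.tsv")
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t",
                             index_label="gene_id")
    paths["expression"] = str(outdir / "expression.tsv")

    (outdir / "truth.json").write_text(cohort.truth.to_json())
    paths["truth"] = str(outdir / "truth.json")
    (outdir / "config.json").write_text(cohort.config.to_json())
    paths["config"] = str(outdir / "config.json")
    return paths


def evaluate_dmr_calls(records, truth: GroundTruth,
                       direction: str = "hyper") -> Dict[str, float]:
    """Per-direction comparison of DMR calls against planted truth.

    The screen for one direction (default hyper, the only direction
    planted) is evaluated on the calls reporting that direction: a call
    (window or segment test flagged as DMR) is a true positive when it
    overlaps a planted window of that direction, a false positive
    otherwise. Sensitivity is the share of planted windows recovered by
    at least one matching call. Calls in the opposite direction belong
    to the other direction's screen and are reported under
    ``n_other_direction_calls``.
    """
    planted = [p for p in truth.planted_regions if p.direction == direction]
    tp = fp = other = 0
    recovered = [False] * len(planted)
    for r in records:
        if not r.is_dmr:
            continue
        if r.direction != direction:
            other += 1
            continue
        hit = False
        for i, p in enumerate(planted):
            if r.interval.overlaps(p.interval):
                hit = True
                recovered[i] = True
        if hit:
            tp += 1
        else:
            fp += 1
    n_calls = tp + fp
    return {
        "n_planted": len(planted),
        "n_calls": n_calls,
        "n_true_calls": tp,
        "n_false_calls": fp,
        "n_other_direction_calls": other,
        "sensitivity": (sum(recovered) / len(planted)) if planted else float("nan"),
        "fdr": (fp / n_calls) if n_calls else 0.0,
    }
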