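"""Region classification, 8-kb three-segment windows, and DMR calling.

A CpG island (CGI) is classified by where it sits relative to gene
models: overlapping a promoter (TSS +/- 2 kb) makes it a promoter CGI;
otherwise overlap with a gene body makes it intragenic; otherwise it is
intergenic. Genes whose promoter overlaps no CGI contribute a non-CGI
promoter region anchored at the TSS.

Each region gets an 8-kb analysis window centered on its anchor (the
TSS for promoter-linked regions, the CGI midpoint otherwise), snapped
outward to the 100-bp bin grid and divided into three near-equal
segments: left shore, core, right shore. Differential methylation
between tumor and normal groups is assessed per window and per segment
by a two-sample t-test on per-sample region means; a segment with
p below its class threshold is an individual DMR.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneModel, GenomicInterval
from .quantify import BIN_SIZE, BinTrack, region_mean

PROMOTER_FLANK = 2_000  # TSS +/- 2 kb defines the promoter region
WINDOW_HALF = 4_000  # 8-kb analysis window

PROMOTER_CGI = "promoter_CGI"
INTRAGENIC_CGI = "intragenic_CGI"
INTERGENIC_CGI = "intergenic_CGI"
NONCGI_PROMOTER = "nonCGI_promoter"
REGION_CLASSES = (PROMOTER_CGI, INTRAGENIC_CGI, INTERGENIC_CGI, NONCGI_PROMOTER)

SEGMENT_ROLES = ("shore_left", "core", "shore_right")
WHOLE_WINDOW = "window"

DEFAULT_THRESHOLDS = {
    PROMOTER_CGI: 0.05,
    INTRAGENIC_CGI: 0.01,
    INTERGENIC_CGI: 0.01,
    NONCGI_PROMOTER: 0.01,
}


@dataclass(frozen=True)
class ClassifiedRegion:
    """A CGI or non-CGI promoter with its class label and window anchor."""

    region_class: str
    anchor: GenomicInterval  # the CGI itself, or the TSS point region
    center: int  # TSS for promoter-linked regions, CGI midpoint otherwise
    gene_id: Optional[str] = None


@dataclass(frozen=True)
class Window:
    """An 8-kb analysis window with its three shore/core/shore segments."""

    interval: GenomicInterval
    segments: tuple[GenomicInterval, GenomicInterval, GenomicInterval]
    truncated: bool
    n_bins: int
    first_bin: int


class TTestResult(NamedTuple):
    t_stat: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class DMRRecord:
    """One tested window or segment with its group means and t-test."""

    interval: GenomicInterval
    region_class: str
    segment: str  # window | shore_left | core | shore_right
    a_tumor: float
    a_normal: float
    n_tumor: int
    n_normal: int
    t_stat: float
    p_value: float
    direction: str  # hyper | hypo
    is_dmr: bool
    gene_id: Optional[str] = None
    degenerate: bool = False
    window_id: Optional[int] = None  # index of the parent region


def _promoter(gene: GeneModel) -> GenomicInterval:
    start = max(0, gene.tss - PROMOTER_FLANK)
    return GenomicInterval(gene.chrom, start, gene.tss + PROMOTER_FLANK, gene.strand)


def classify_regions(
    genes: Sequence[GeneModel], cgis: Sequence[GenomicInterval]
) -> list[ClassifiedRegion]:
    """Assign each CGI exactly one class and emit non-CGI promoters.

    Precedence: promoter > intragenic > intergenic. A promoter CGI is
    linked to the gene with the nearest TSS among those whose promoter
    it overlaps; its window centers on that TSS. Intragenic/intergenic
    windows center on the CGI midpoint.
    """
    regions: list[ClassifiedRegion] = []
    genes_by_chrom: Dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    cgi_promoter_hit: Dict[int, bool] = {}
    gene_has_cgi = {g.gene_id: False for g in genes}
    for idx, cgi in enumerate(cgis):
        overlapping = [
            g
            for g in genes_by_chrom.get(cgi.chrom, ())
            if cgi.overlaps(_promoter(g))
        ]
        if overlapping:
            midpoint = (cgi.start + cgi.end) // 2
            nearest = min(overlapping, key=lambda g: (abs(g.tss - midpoint), g.gene_id))
            for g in overlapping:
                gene_has_cgi[g.gene_id] = True
            regions.append(
                ClassifiedRegion(PROMOTER_CGI, cgi, nearest.tss, nearest.gene_id)
            )
            continue
        body_hits = [
            g for g in genes_by_chrom.get(cgi.chrom, ()) if cgi.overlaps(g.body)
        ]
        center = (cgi.start + cgi.end) // 2
        if body_hits:
            host = min(body_hits, key=lambda g: (abs(g.tss - center), g.gene_id))
            regions.append(ClassifiedRegion(INTRAGENIC_CGI, cgi, center, host.gene_id))
        else:
            regions.append(ClassifiedRegion(INTERGENIC_CGI, cgi, center, None))

    for g in genes:
        if not gene_has_cgi[g.gene_id]:
            regions.append(
                ClassifiedRegion(NONCGI_PROMOTER, _promoter(g), g.tss, g.gene_id)
            )
    return regions


def build_window(
    region: ClassifiedRegion,
    chrom_length: int,
    bin_size: int = BIN_SIZE,
    segmentation: str = "thirds",
) -> Window:
    """Build the 8-kb window around the region center.

    The nominal span [center-4000, center+4000) is snapped outward to
    the bin grid. With ``segmentation="thirds"`` (default) the snapped
    span is divided into three near-equal segments (boundaries at
    floor(i*L/3), i.e. 2666/2667/2667 for an 8,000-bp window);
    ``"shore2k"`` uses fixed 2-kb shores around a central core
    (2000/4000/2000 for 8,000 bp). Windows extending past either
    chromosome end are flagged truncated and excluded from testing
    downstream.
    """
    if segmentation not in ("thirds", "shore2k"):
        raise ValueError(f"unknown segmentation mode {segmentation!r}")
    if region.center < 0:
        raise ValueError(f"negative window center: {region}")
    nominal_start = region.center - WINDOW_HALF
    nominal_end = region.center + WINDOW_HALF
    start = (nominal_start // bin_size) * bin_size if nominal_start >= 0 else nominal_start
    end = math.ceil(nominal_end / bin_size) * bin_size
    truncated = start < 0 or end > chrom_length
    chrom = region.anchor.chrom
    w_start = max(0, start)
    w_end = min(end, int(chrom_length)) if truncated else end
    interval = GenomicInterval(chrom, w_start, w_end)
    length = w_end - w_start
    if segmentation == "thirds":
        bounds = [w_start + (i * length) // 3 for i in range(4)]
    else:
        shore = min(2_000, length // 3)
        bounds = [w_start, w_start + shore, w_end - shore, w_end]
    segments = tuple(
        GenomicInterval(chrom, bounds[i], bounds[i + 1]) for i in range(3)
    )
    return Window(
        interval=interval,
        segments=segments,  # type: ignore[arg-type]
        truncated=truncated,
        n_bins=(len(interval) + bin_size - 1) // bin_size,
        first_bin=interval.start // bin_size,
    )


def segment_t_test(
    tumor_means: Sequence[float],
    normal_means: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test on per-sample region means.

    Default is the classical pooled-variance Student test with
    df = S_tumor + S_normal - 2; Welch's unequal-variance form is
    available via ``welch=True``. Degenerate zero-variance inputs are
    resolved explicitly: identical constant groups give t=0, p=1;
    constant groups with different means give p=0 with a degenerate
    flag.
    """
    x = np.asarray(tumor_means, dtype=float)
    y = np.asarray(normal_means, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 samples per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TTestResult(0.0, 1.0, False)
        sign = -1.0 if x.mean() < y.mean() else 1.0
        return TTestResult(sign * math.inf, 0.0, True)
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(float(t), float(p), False)


def _group_region_means(
    tracks: Sequence[BinTrack], region: GenomicInterval
) -> np.ndarray:
    return np.array([region_mean(t, region) for t in tracks])


def call_dmrs(
    regions: Sequence[ClassifiedRegion],
    tumor_tracks: Sequence[BinTrack],
    normal_tracks: Sequence[BinTrack],
    chrom_lengths: Mapping[str, int],
    thresholds: Optional[Mapping[str, float]] = None,
    welch: bool = False,
    test_whole_window: bool = True,
    segmentation: str = "thirds",
    strand_aware_shores: bool = False,
) -> list[DMRRecord]:
    """Test every non-truncated window and its three segments.

    Emits one record per test (whole window plus each segment, labeled);
    a segment record with ``p < thresholds[region_class]`` is marked an
    individual DMR. Shore labels are genomic left/right by default;
    ``strand_aware_shores`` swaps them to upstream/downstream order for
    minus-strand promoter regions. Output is sorted by p-value.
    """
    if len(tumor_tracks) < 2 or len(normal_tracks) < 2:
        raise ValueError("need >= 2 tracks per group")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    records: list[DMRRecord] = []
    for region_idx, region in enumerate(regions):
        chrom = region.anchor.chrom
        window = build_window(region, chrom_lengths[chrom], segmentation=segmentation)
        if window.truncated:
            continue
        roles = list(SEGMENT_ROLES)
        if strand_aware_shores and region.anchor.strand == "-":
            roles = [roles[2], roles[1], roles[0]]
        parts: list[tuple[str, GenomicInterval]] = []
        if test_whole_window:
            parts.append((WHOLE_WINDOW, window.interval))
        parts.extend(zip(roles, window.segments))
        for role, iv in parts:
            tm = _group_region_means(tumor_tracks, iv)
            nm = _group_region_means(normal_tracks, iv)
            res = segment_t_test(tm, nm, welch=welch)
            direction = "hyper" if tm.mean() > nm.mean() else "hypo"
            records.append(
                DMRRecord(
                    interval=iv,
                    region_class=region.region_class,
                    segment=role,
                    a_tumor=float(tm.mean()),
                    a_normal=float(nm.mean()),
                    n_tumor=len(tm),
                    n_normal=len(nm),
                    t_stat=res.t_stat,
                    p_value=res.p_value,
                    direction=direction,
                    is_dmr=bool(res.p_value < thr[region.region_class]),
                    gene_id=region.gene_id,
                    degenerate=res.degenerate,
                    window_id=region_idx,
                )
            )
    return sorted(records, key=lambda r: (r.p_value, r.interval.chrom, r.interval.start))


def bh_adjust(records: Sequence[DMRRecord],
              thresholds: Optional[Mapping[str, float]] = None) -> list[DMRRecord]:
    """Optional Benjamini-Hochberg recalibration of the is_dmr flags.

    Replaces each record's DMR flag with BH(q = class threshold) applied
    across all emitted tests; p-values themselves are left untouched.
    """
    from statsmodels.stats.multitest import multipletests

    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    out: list[DMRRecord] = []
    pvals = np.array([r.p_value for r in records])
    for cls in REGION_CLASSES:
        idx = [i for i, r in enumerate(records) if r.region_class == cls]
        if not idx:
            continue
        reject, *_ = multipletests(pvals[idx], alpha=thr[cls], method="fdr_bh")
        for i, rej in zip(idx, reject):
            out.append(replace(records[i], is_dmr=bool(rej)))
    return sorted(out, key=lambda r: (r.p_value, r.interval.chrom, r.interval.start))


def summarize_fractions(
    dmrs: Sequence[DMRRecord], regions: Sequence[ClassifiedRegion]
) -> dict:
    """Per-class counts of tested regions and regions with >= 1 DMR segment.

    A region is counted differential when any of its segment tests is a
    DMR. Fractions are None (undefined) for classes with zero tested
    regions. Also reports the segment-level core-vs-shore breakdown of
    DMR calls.
    """
    tested_keys: Dict[str, set] = {c: set() for c in REGION_CLASSES}
    called_keys: Dict[str, set] = {c: set() for c in REGION_CLASSES}
    core_shore = {"core": 0, "shore": 0}
    for r in dmrs:
        tested_keys[r.region_class].add(r.window_id)
        if r.segment != WHOLE_WINDOW and r.is_dmr:
            called_keys[r.region_class].add(r.window_id)
            core_shore["core" if r.segment == "core" else "shore"] += 1
    out = {"classes": {}, "segment_calls": core_shore}
    for cls in REGION_CLASSES:
        n_tested = len(tested_keys[cls])
        n_called = len(called_keys[cls])
        out["classes"][cls] = {
            "n_tested": n_tested,
            "n_differential": n_called,
            "fraction": (n_called / n_tested) if n_tested else None,
        }
    out["n_regions_total"] = len(regions)
    return out
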