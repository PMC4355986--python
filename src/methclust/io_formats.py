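"""Readers and writers for the plain-text formats the pipeline touches.

All interval formats follow the BED convention (0-based, half-open).
Chromosome names are opaque strings; no ``chr``-prefix normalization is
attempted. Every parser validates rather than silently coercing: a
malformed row raises :class:`ParseError` naming the offending line.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

STRAND_UNKNOWN = "."


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unknown); ``score`` is an
    optional real used e.g. for bedGraph values or -log10 P in BED output.
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end <= start: {self}")
        if self.strand not in ("+", "-", STRAND_UNKNOWN):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a single TSS, used as the anchor for promoter windows."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_start: int
    gene_end: int
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+":
            if not (self.gene_start <= self.tss < self.gene_end):
                raise ValueError(
                    f"gene {self.gene_id}: TSS {self.tss} outside "
                    f"[{self.gene_start}, {self.gene_end}) on + strand"
                )
        else:
            if not (self.gene_start < self.tss <= self.gene_end):
                raise ValueError(
                    f"gene {self.gene_id}: TSS {self.tss} outside "
                    f"({self.gene_start}, {self.gene_end}] on - strand"
                )

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.gene_start, self.gene_end, self.strand)


@dataclass(frozen=True)
class SampleRecord:
    """One row of the clinical sample sheet."""

    sample_id: str
    group: str  # tumor | normal | cell_line
    er_status: str = "unknown"  # positive | negative | unknown
    age: Optional[float] = None
    grade: Optional[int] = None
    os_time: Optional[float] = None
    os_event: Optional[int] = None  # 1 = death, 0 = censored

    def __post_init__(self) -> None:
        if self.group not in ("tumor", "normal", "cell_line"):
            raise ValueError(f"sample {self.sample_id}: unknown group {self.group!r}")
        if self.er_status not in ("positive", "negative", "unknown"):
            raise ValueError(
                f"sample {self.sample_id}: unknown ER status {self.er_status!r}"
            )
        if self.os_event is not None and self.os_event not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id}: os_event must be 0 or 1, got {self.os_event}"
            )
        if self.os_time is not None and self.os_time <= 0:
            raise ValueError(f"sample {self.sample_id}: os_time must be > 0")


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_intervals(path, dialect: str = "bed") -> list[GenomicInterval]:
    """Read BED or bedGraph intervals.

    ``bed`` maps column 5 (if present) to score and column 6 to strand;
    ``bedgraph`` maps column 4 to score. Track and comment lines are
    skipped. Malformed coordinates raise :class:`ParseError` with the
    line number.
    """
    if dialect not in ("bed", "bedgraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start < 0 or end <= start:
            raise ParseError(
                f"{path}:{lineno}: invalid interval [{start}, {end})"
            )
        score: Optional[float] = None
        strand = STRAND_UNKNOWN
        if dialect == "bedgraph":
            if len(fields) >= 4:
                try:
                    score = float(fields[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad bedGraph score") from exc
        else:
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad BED score") from exc
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
        out.append(GenomicInterval(chrom, start, end, strand, score))
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path, names=None) -> None:
    """Write intervals as BED6 (name defaults to ``region_<i>``)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "start", "end", "cluster_id"]


def read_gene_table(path) -> list[GeneModel]:
    """Read the gene model TSV (header: gene_id chrom strand tss start end
    cluster_id; cluster_id may be NA).

    Validates strand/TSS invariants, rejects duplicate gene ids and
    clusters spanning more than one chromosome; returns genes sorted by
    (chrom, tss).
    """
    path = Path(path)
    genes: list[GeneModel] = []
    header: Optional[list[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            if header != _GENE_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected header {_GENE_COLUMNS}, got {header}"
                )
            continue
        if len(fields) != len(_GENE_COLUMNS):
            raise ParseError(f"{path}:{lineno}: wrong column count")
        row = dict(zip(_GENE_COLUMNS, fields))
        cluster = None if row["cluster_id"] in ("NA", "", ".") else row["cluster_id"]
        try:
            gene = GeneModel(
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                tss=int(row["tss"]),
                gene_start=int(row["start"]),
                gene_end=int(row["end"]),
                cluster_id=cluster,
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        genes.append(gene)
    ids = Counter(g.gene_id for g in genes)
    dupes = [g for g, n in ids.items() if n > 1]
    if dupes:
        raise ParseError(f"{path}: duplicate gene_id(s): {sorted(dupes)}")
    by_cluster: dict[str, set[str]] = {}
    for g in genes:
        if g.cluster_id is not None:
            by_cluster.setdefault(g.cluster_id, set()).add(g.chrom)
    for cid, chroms in by_cluster.items():
        if len(chroms) > 1:
            raise ParseError(
                f"{path}: cluster {cid} spans chromosomes {sorted(chroms)}"
            )
    return sorted(genes, key=lambda g: (g.chrom, g.tss))


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            cid = g.cluster_id if g.cluster_id is not None else "NA"
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{g.gene_start}\t{g.gene_end}\t{cid}\n"
            )


_SAMPLE_COLUMNS = [
    "sample_id", "group", "er_status", "age", "grade", "os_time", "os_event",
]


def _maybe(value: str, caster):
    return None if value in ("NA", "", ".") else caster(value)


def read_sample_sheet(path) -> list[SampleRecord]:
    """Read the clinical sample sheet TSV; ``NA`` marks missing values."""
    path = Path(path)
    records: list[SampleRecord] = []
    header: Optional[list[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            if header != _SAMPLE_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected header {_SAMPLE_COLUMNS}, got {header}"
                )
            continue
        if len(fields) != len(_SAMPLE_COLUMNS):
            raise ParseError(f"{path}:{lineno}: wrong column count")
        row = dict(zip(_SAMPLE_COLUMNS, fields))
        try:
            rec = SampleRecord(
                sample_id=row["sample_id"],
                group=row["group"],
                er_status=row["er_status"] if row["er_status"] not in ("NA", "") else "unknown",
                age=_maybe(row["age"], float),
                grade=_maybe(row["grade"], int),
                os_time=_maybe(row["os_time"], float),
                os_event=_maybe(row["os_event"], int),
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    counts = Counter(r.group for r in records)
    logger.info("sample sheet %s: %s", path, dict(counts))
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path) -> None:
    def fmt(v):
        return "NA" if v is None else (f"{v:g}" if isinstance(v, float) else str(v))

    with open(path, "w") as fh:
        fh.write("\t".join(_SAMPLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [r.sample_id, r.group, r.er_status,
                     fmt(r.age), fmt(r.grade), fmt(r.os_time), fmt(r.os_event)]
                )
                + "\n"
            )


_DMR_TSV_COLUMNS = [
    "chrom", "start", "end", "name", "region_class", "segment", "strand",
    "a_tumor", "a_normal", "t_stat", "p_value", "direction", "is_dmr",
]


def write_dmr_output(dmrs, bed_path, tsv_path) -> None:
    """Write DMR calls as a BED6 (score = -log10 P, capped at 320) plus a
    companion TSV carrying the full test record.

    Round-tripping the BED through :func:`read_intervals` preserves every
    (chrom, start, end) exactly.
    """
    with open(bed_path, "w") as bed, open(tsv_path, "w") as tsv:
        tsv.write("\t".join(_DMR_TSV_COLUMNS) + "\n")
        for i, d in enumerate(dmrs):
            iv = d.interval
            if d.p_value > 0:
                score = -math.log10(d.p_value)
            else:
                score = 320.0  # cap for degenerate p = 0
            name = f"dmr_{i}_{d.segment}"
            bed.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
            tsv.write(
                "\t".join(
                    [
                        iv.chrom, str(iv.start), str(iv.end), name,
                        d.region_class, d.segment, iv.strand,
                        f"{d.a_tumor:.6g}", f"{d.a_normal:.6g}",
                        f"{d.t_stat:.6g}", f"{d.p_value:.6g}",
                        d.direction, str(int(d.is_dmr)),
                    ]
                )
                + "\n"
            )
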