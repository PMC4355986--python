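"""Bin-level methylation quantification for MBD-capture sequencing.

MBD-seq measures methylation as enrichment read density. Each chromosome
is tiled with fixed 100-bp bins starting at coordinate 0; a read
increments every bin it overlaps by at least one base (no fractional
attribution). Raw bin counts are made comparable across libraries by
dividing by a mantissa-style factor derived from the library size:

    N_read,i = U_read,i / (N_U / 10^floor(log10 N_U))

where U_read,i is the unique-read count of bin i and N_U the total
number of uniquely mapped reads. The factor N_U / 10^floor(log10 N_U)
is the leading mantissa of N_U and always lies in [1, 10).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import GenomicInterval

logger = logging.getLogger(__name__)

BIN_SIZE = 100


def normalization_factor(n_unique_reads: int) -> float:
    """Library-size normalization factor: the mantissa of ``N_U``.

    Returns ``N_U / 10^floor(log10 N_U)``, a value in ``[1, 10)``.
    The exponent is computed from the decimal digit count so exact
    powers of ten are not perturbed by floating-point log10.
    """
    n = int(n_unique_reads)
    if n < 1:
        raise ValueError(f"library size must be >= 1, got {n_unique_reads}")
    exponent = len(str(n)) - 1  # floor(log10 n) exactly, for integer n
    return n / 10.0 ** exponent


def _n_bins(chrom_length: int, bin_size: int = BIN_SIZE) -> int:
    return (int(chrom_length) + bin_size - 1) // bin_size


def bin_counts(
    reads: Iterable[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    bin_size: int = BIN_SIZE,
    exclusion_mask: Optional[Sequence[GenomicInterval]] = None,
) -> tuple[Dict[str, np.ndarray], int]:
    """Count reads per fixed-width bin.

    Bins tile each chromosome from 0 in ``bin_size`` steps (the last bin
    may be short). A read increments every bin it overlaps by >= 1 bp.
    Reads overlapping ``exclusion_mask`` (e.g. satellite repeats) are
    dropped entirely before counting.

    Returns ``(counts_by_chrom, n_retained_reads)`` where the retained
    count is the library size ``N_U`` after masking.
    """
    counts = {
        chrom: np.zeros(_n_bins(length, bin_size), dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    mask_by_chrom: Dict[str, list[tuple[int, int]]] = {}
    if exclusion_mask:
        for iv in exclusion_mask:
            mask_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    retained = 0
    for read in reads:
        if read.chrom not in counts:
            raise ValueError(f"read on unknown chromosome: {read}")
        if read.end > chrom_lengths[read.chrom]:
            raise ValueError(
                f"read beyond chromosome end ({chrom_lengths[read.chrom]} bp): {read}"
            )
        masked = any(
            read.start < m_end and m_start < read.end
            for m_start, m_end in mask_by_chrom.get(read.chrom, ())
        )
        if masked:
            continue
        retained += 1
        first = read.start // bin_size
        last = (read.end - 1) // bin_size  # end is exclusive
        counts[read.chrom][first : last + 1] += 1
    return counts, retained


@dataclass
class BinTrack:
    """Per-sample raw and normalized 100-bp bin counts.

    ``raw[chrom][i]`` is the unique-read count of bin i and
    ``normalized[chrom][i]`` the library-size-normalized value
    ``raw / norm_factor``.
    """

    sample_id: str
    raw: Dict[str, np.ndarray]
    normalized: Dict[str, np.ndarray]
    n_unique_reads: int
    norm_factor: float
    bin_size: int = BIN_SIZE

    @property
    def chroms(self) -> list[str]:
        return list(self.raw)


def normalize(
    raw_counts: Mapping[str, np.ndarray],
    n_unique_reads: int,
    sample_id: str = "sample",
    bin_size: int = BIN_SIZE,
) -> BinTrack:
    """Divide every bin count by the library-size normalization factor.

    ``n_unique_reads`` should equal the number of reads retained after
    masking; a mismatch with the counted total larger than what bin
    double-counting can explain is logged as a warning, not an error
    (reads spanning bin boundaries legitimately inflate the bin sum).
    """
    factor = normalization_factor(n_unique_reads)
    bin_sum = int(sum(int(c.sum()) for c in raw_counts.values()))
    # each read hits >= 1 bin, so the bin sum can only exceed N_U
    if bin_sum < n_unique_reads:
        logger.warning(
            "sample %s: bin-count sum %d below stated library size %d",
            sample_id, bin_sum, n_unique_reads,
        )
    normalized = {
        chrom: counts.astype(float) / factor for chrom, counts in raw_counts.items()
    }
    return BinTrack(
        sample_id=sample_id,
        raw={c: np.asarray(v, dtype=np.int64) for c, v in raw_counts.items()},
        normalized=normalized,
        n_unique_reads=int(n_unique_reads),
        norm_factor=factor,
        bin_size=bin_size,
    )


def quantify_sample(
    reads: Iterable[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    sample_id: str = "sample",
    bin_size: int = BIN_SIZE,
    exclusion_mask: Optional[Sequence[GenomicInterval]] = None,
) -> BinTrack:
    """Full path from aligned-read intervals to a normalized BinTrack."""
    raw, retained = bin_counts(reads, chrom_lengths, bin_size, exclusion_mask)
    return normalize(raw, retained, sample_id=sample_id, bin_size=bin_size)


def overlapping_bin_range(
    region: GenomicInterval, bin_size: int = BIN_SIZE
) -> tuple[int, int]:
    """Half-open bin-index range [first, last) of bins overlapping region."""
    return region.start // bin_size, (region.end - 1) // bin_size + 1


def region_mean(track: BinTrack, region: GenomicInterval) -> float:
    """Mean normalized count over all bins overlapping the region by >= 1 bp.

    Partially overlapped bins enter at full weight, consistent with the
    whole-or-part counting rule.
    """
    if region.chrom not in track.normalized:
        raise ValueError(f"region on unknown chromosome: {region.chrom}")
    vec = track.normalized[region.chrom]
    first, last = overlapping_bin_range(region, track.bin_size)
    if first >= len(vec):
        raise ValueError(f"region beyond chromosome bounds: {region}")
    last = min(last, len(vec))
    return float(vec[first:last].mean())


def write_track_bedgraph(track: BinTrack, path) -> None:
    """Write the normalized track as bedGraph (non-zero bins only)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample_id}"\n')
        for chrom, vec in track.normalized.items():
            nz = np.nonzero(vec)[0]
            for i in nz:
                start = int(i) * track.bin_size
                end = start + track.bin_size
                fh.write(f"{chrom}\t{start}\t{end}\t{vec[i]:g}\n")


def read_track_bedgraph(path, chrom_lengths: Mapping[str, int],
                        n_unique_reads: int, sample_id: str = "sample",
                        bin_size: int = BIN_SIZE) -> BinTrack:
    """Rebuild a BinTrack from a bedGraph written by write_track_bedgraph."""
    from .io_formats import read_intervals

    factor = normalization_factor(n_unique_reads)
    normalized = {
        chrom: np.zeros(_n_bins(length, bin_size))
        for chrom, length in chrom_lengths.items()
    }
    for iv in read_intervals(path, dialect="bedgraph"):
        normalized[iv.chrom][iv.start // bin_size] = iv.score or 0.0
    raw = {c: np.rint(v * factor).astype(np.int64) for c, v in normalized.items()}
    return BinTrack(sample_id, raw, normalized, int(n_unique_reads), factor, bin_size)
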