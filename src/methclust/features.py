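"""GC-content and conservation metagene profiles around the TSS.

For each gene an 8,000-bp window spanning 4 kb upstream to 4 kb
downstream of the TSS is divided into 160 bins of 50 bp. GC content is
(G+C)/50 per bin (ambiguous bases count as non-GC so the denominator
stays 50); conservation is the mean of the available per-base scores
in each bin (bases without a score are excluded, a fully unscored bin
is missing). Minus-strand windows are orientation-flipped so bin 0 is
always 4 kb upstream in transcription sense. Cluster summaries report
the per-bin mean and sample (n-1) standard deviation over member
genes, with the whole gene set as background.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomicInterval

N_BINS = 160
BIN_BP = 50
FLANK = 4_000
WINDOW_BP = N_BINS * BIN_BP  # 8,000

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def tss_window_sequence(gene: GeneModel, genome: Mapping[str, str]) -> Optional[str]:
    """The 8-kb sequence around the TSS, in transcription orientation.

    Returns None (gene skipped) when the window would run off either
    chromosome end. ``genome`` maps chromosome name to sequence; a
    pyfaidx.Fasta works directly.
    """
    seq = genome[gene.chrom]
    chrom_len = len(seq)
    start, end = gene.tss - FLANK, gene.tss + FLANK
    if start < 0 or end > chrom_len:
        return None
    window = str(seq[start:end])
    if gene.strand == "-":
        window = window.translate(_COMPLEMENT)[::-1]
    return window


def gc_profile(sequence: str) -> np.ndarray:
    """Per-50-bp-bin GC fraction of an 8,000-bp sequence."""
    if len(sequence) != WINDOW_BP:
        raise ValueError(f"expected {WINDOW_BP}-bp sequence, got {len(sequence)}")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    return is_gc.reshape(N_BINS, BIN_BP).sum(axis=1) / BIN_BP


def per_base_scores(
    track: Sequence[GenomicInterval], chrom: str, start: int, end: int
) -> np.ndarray:
    """Expand a bedGraph-style interval track to per-base values over
    [start, end); unscored bases are NaN."""
    out = np.full(end - start, np.nan)
    for iv in track:
        if iv.chrom != chrom or iv.score is None:
            continue
        lo, hi = max(iv.start, start), min(iv.end, end)
        if lo < hi:
            out[lo - start : hi - start] = iv.score
    return out


def conservation_profile(
    track: Sequence[GenomicInterval],
    gene: GeneModel,
    chrom_length: Optional[int] = None,
) -> Optional[np.ndarray]:
    """Per-bin mean conservation around the TSS, strand-oriented.

    Bases without a score are excluded from the bin mean; a bin with no
    scored base is NaN. Returns None when the window is truncated by a
    chromosome end (requires ``chrom_length``).
    """
    start, end = gene.tss - FLANK, gene.tss + FLANK
    if start < 0 or (chrom_length is not None and end > chrom_length):
        return None
    base = per_base_scores(track, gene.chrom, start, end)
    if gene.strand == "-":
        base = base[::-1]
    binned = base.reshape(N_BINS, BIN_BP)
    counts = np.sum(~np.isnan(binned), axis=1)
    sums = np.nansum(binned, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def profile_matrix(
    genes: Sequence[GeneModel],
    genome: Optional[Mapping[str, str]] = None,
    conservation_track: Optional[Sequence[GenomicInterval]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Stack per-gene 160-bin profiles into a genes x 160 DataFrame.

    Exactly one of ``genome`` (GC profiles) or ``conservation_track``
    must be given. Genes whose window is truncated are skipped.
    """
    if (genome is None) == (conservation_track is None):
        raise ValueError("give exactly one of genome or conservation_track")
    rows, index = [], []
    for gene in genes:
        if genome is not None:
            seq = tss_window_sequence(gene, genome)
            if seq is None:
                continue
            rows.append(gc_profile(seq))
        else:
            length = None if chrom_lengths is None else chrom_lengths.get(gene.chrom)
            prof = conservation_profile(conservation_track, gene, length)
            if prof is None:
                continue
            rows.append(prof)
        index.append(gene.gene_id)
    cols = [f"bin_{i:03d}" for i in range(N_BINS)]
    return pd.DataFrame(rows, index=index, columns=cols)


@dataclass
class ProfileSummary:
    """Per-bin cluster mean/sd against the background mean."""

    cluster_mean: np.ndarray
    cluster_sd: np.ndarray  # sample (n-1) sd; 0 for a single member
    background_mean: np.ndarray
    n_members: int
    n_background: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(N_BINS),
                "offset_bp": np.arange(N_BINS) * BIN_BP - FLANK,
                "mean": self.cluster_mean,
                "sd": self.cluster_sd,
                "background_mean": self.background_mean,
            }
        )


def cluster_profile_summary(
    profiles: pd.DataFrame,
    member_ids: Iterable[str],
    background_ids: Optional[Iterable[str]] = None,
) -> ProfileSummary:
    """Summarize member-gene profiles per bin against a background set.

    Means and sds are computed over non-missing entries only; sd is the
    sample (n-1) standard deviation (0 when a bin has one member).
    Background defaults to every profiled gene.
    """
    members = [g for g in member_ids if g in profiles.index]
    if not members:
        raise ValueError("empty member set")
    bg = (
        list(profiles.index)
        if background_ids is None
        else [g for g in background_ids if g in profiles.index]
    )
    sub = profiles.loc[members].to_numpy()
    bgm = profiles.loc[bg].to_numpy()
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(sub, axis=0)
        n_eff = np.sum(~np.isnan(sub), axis=0)
        sd = np.nanstd(sub, axis=0, ddof=1) if sub.shape[0] > 1 else np.zeros(N_BINS)
        sd = np.where(n_eff > 1, sd, 0.0)
        background = np.nanmean(bgm, axis=0)
    return ProfileSummary(
        cluster_mean=mean,
        cluster_sd=sd,
        background_mean=background,
        n_members=len(members),
        n_background=len(bg),
    )
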