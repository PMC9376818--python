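"""Promoter and nucleosome-window signal quantification.

Window geometry follows the metaprofile convention used for mononucleosomal
ChIP-seq: around each TSS three strand-oriented windows are averaged — the
−1 nucleosome at offsets [−500, −100), the nucleosome-depleted TSS at
[−20, +21), and the +1 nucleosome at [+100, +501).  Offsets are transcribed
direction; offset 0 is the TSS base.  Promoter enrichment is RPKM over
TSS ± 1 kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from embryoz.genome_io import CoverageTrack, GeneRecord, Interval

# strand-oriented windows as [start_offset, end_offset) relative to the TSS
WINDOW_MINUS1 = (-500, -100)
WINDOW_TSS = (-20, 21)
WINDOW_PLUS1 = (100, 501)

FRAGMENT_LENGTH = 150  # mononucleosomal fragment length assumed throughout


@dataclass(frozen=True)
class PromoterSignal:
    """Per-gene promoter enrichment and the three nucleosome-window means."""

    gene_id: str
    rpkm_promoter: float
    mean_minus1: float
    mean_tss: float
    mean_plus1: float


def promoter_window(
    gene: GeneRecord, half_width: int = 1000, chrom_length: Optional[int] = None
) -> Interval:
    """The symmetric promoter span [tss − half_width, tss + half_width).

    The span is strand-independent (only window *means* are strand
    oriented).  Windows running off a chromosome end are clipped with a
    warning.
    """
    start, end = gene.tss - half_width, gene.tss + half_width
    clipped_start = max(start, 0)
    clipped_end = min(end, chrom_length) if chrom_length is not None else end
    if clipped_start != start or clipped_end != end:
        warnings.warn(
            f"promoter window of {gene.gene_id} clipped to "
            f"[{clipped_start}, {clipped_end})",
            stacklevel=2,
        )
    return Interval(gene.chrom, clipped_start, clipped_end, name=gene.gene_id)


def _oriented_slice(track: CoverageTrack, gene: GeneRecord, lo: int, hi: int) -> np.ndarray:
    """Per-base values at transcribed-direction offsets [lo, hi) from the TSS."""
    if gene.strand == "+":
        start, end = gene.tss + lo, gene.tss + hi
        if start < 0 or end > len(track):
            raise ValueError(f"window [{start},{end}) off chromosome for {gene.gene_id}")
        return track.values[start:end]
    # minus strand: offset d maps to genomic tss - d
    start, end = gene.tss - (hi - 1), gene.tss - lo + 1
    if start < 0 or end > len(track):
        raise ValueError(f"window [{start},{end}) off chromosome for {gene.gene_id}")
    return track.values[start:end][::-1]


def window_means(track: CoverageTrack, gene: GeneRecord) -> tuple[float, float, float]:
    """Mean per-base RPM in the −1-nucleosome, TSS and +1-nucleosome windows.

    Windows are strand-oriented: for a minus-strand gene the −1 window lies
    downstream in genomic coordinates.
    """
    scale = track.library_size / 1e6
    return tuple(
        float(_oriented_slice(track, gene, lo, hi).mean() / scale)
        for lo, hi in (WINDOW_MINUS1, WINDOW_TSS, WINDOW_PLUS1)
    )


def promoter_rpkm(
    track: CoverageTrack, window: Interval, fragment_length: int = FRAGMENT_LENGTH
) -> float:
    """Reads per kilobase per million mapped reads over a window.

    Read-equivalents are recovered from the base-coverage sum divided by the
    fragment length, so the value is invariant to how the same coverage is
    binned.
    """
    if len(window) == 0:
        raise ValueError("zero-length window")
    reads = float(track.values[window.start : window.end].sum()) / fragment_length
    kb = len(window) / 1000.0
    millions = track.library_size / 1e6
    return reads / (kb * millions)


def quantify_promoters(
    track: CoverageTrack,
    genes: Sequence[GeneRecord],
    half_width: int = 1000,
    fragment_length: int = FRAGMENT_LENGTH,
) -> list[PromoterSignal]:
    """Promoter RPKM plus the three window means for every gene."""
    out = []
    for gene in genes:
        window = promoter_window(gene, half_width, chrom_length=len(track))
        m, t, p = window_means(track, gene)
        out.append(
            PromoterSignal(gene.gene_id, promoter_rpkm(track, window, fragment_length), m, t, p)
        )
    return out


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each sample column across all promoters (population sd).

    Raises on a zero-variance column, naming the sample.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 promoters to Z-score")
    sd = matrix.std(axis=0, ddof=0)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance sample column(s): {dead}")
    return (matrix - matrix.mean(axis=0)) / sd


def count_cpg(sequence: str, window: Optional[Interval] = None) -> int:
    """Count CpG dinucleotides in a window, forward strand, case-insensitive.

    CpG is its own reverse complement at the dinucleotide level, so one
    strand suffices.  The scan is overlap-free, but "CG" cannot overlap
    itself so plain counting is exact.  N bases never match.
    """
    if window is not None:
        sequence = sequence[window.start : window.end]
    return sequence.upper().count("CG")


def bin_genome(track: CoverageTrack, bin_size: int = 5000,
               fragment_length: int = FRAGMENT_LENGTH) -> np.ndarray:
    """RPKM per non-overlapping genomic bin; the last partial bin is kept and
    normalized by its true length."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = len(track)
    edges = np.arange(0, n + bin_size, bin_size)
    edges[-1] = min(edges[-1], n)
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    sums = np.add.reduceat(track.values, edges[:-1])
    lengths = np.diff(edges)
    reads = sums / fragment_length
    return reads / ((lengths / 1000.0) * (track.library_size / 1e6))


def correlation_cluster(samples: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between sample columns and an average-linkage
    dendrogram order on distance 1 − r."""
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 rows to correlate samples")
    if samples.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    corr = samples.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry for squareform
    linkage = average(squareform(dist, checks=False))
    order = [samples.columns[i] for i in leaves_list(linkage)]
    return corr, order


def kmeans_promoters(
    matrix: pd.DataFrame, k: int = 4, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """Partition promoters into k clusters on their stage profiles.

    Lloyd k-means with ``n_init`` random restarts, best inertia kept;
    deterministic under a fixed seed.  Returns integer labels indexed by
    gene.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes {matrix.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="random",
                algorithm="lloyd")
    labels = km.fit_predict(matrix.to_numpy())
    return pd.Series(labels, index=matrix.index, name="cluster")
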