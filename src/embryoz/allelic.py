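"""Allele-specific peak classification by exact binomial test.

Each peak carries paternal and maternal read counts (allele assignment is
upstream, from SNP-resolved alignment or the synthetic generator).  Peaks
with fewer than 10 SNP-trackable reads are untrackable and excluded from
testing — the multiple-testing family is the trackable set.  A trackable
peak is paternal-biased when its allelic ratio paternal/(paternal+maternal)
is ≥ 0.85 with adjusted P < 0.05, maternal-biased at ratio ≤ 0.15 with
adjusted P < 0.05, and biallelic otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

MIN_TRACKABLE_READS = 10
RATIO_PATERNAL = 0.85
RATIO_MATERNAL = 0.15
ALPHA = 0.05


@dataclass
class AllelicPeakRecord:
    peak_id: str
    paternal_reads: int
    maternal_reads: int
    allelic_ratio: Optional[float] = None
    p_value: Optional[float] = None
    p_adjusted: Optional[float] = None
    label: Optional[str] = None


def allelic_ratio(paternal: int, maternal: int) -> Optional[float]:
    """Paternal reads over total reads; None when there are no reads."""
    if paternal < 0 or maternal < 0:
        raise ValueError("read counts must be nonnegative")
    total = paternal + maternal
    if total == 0:
        return None
    return paternal / total


def binom_exact_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial P: total probability of outcomes no more
    likely than the observed one under Binomial(n, p0).

    At p0 = 0.5 this equals the doubled symmetric tail, capped at 1.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)


def bh_adjust(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving).

    ``method`` accepts any statsmodels multipletests method name
    (e.g. "bonferroni").
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def classify_allelic(
    records: Iterable[AllelicPeakRecord | tuple],
    min_reads: int = MIN_TRACKABLE_READS,
    ratio_hi: float = RATIO_PATERNAL,
    ratio_lo: float = RATIO_MATERNAL,
    alpha: float = ALPHA,
    adjust_method: str = "fdr_bh",
) -> tuple[list[AllelicPeakRecord], dict]:
    """Label every peak paternal / maternal / biallelic / untrackable.

    Returns the labelled records and a summary with per-label counts and the
    fraction biallelic among trackable peaks.
    """
    recs: list[AllelicPeakRecord] = []
    for r in records:
        if isinstance(r, AllelicPeakRecord):
            recs.append(r)
        else:
            pid, pat, mat = r
            recs.append(AllelicPeakRecord(str(pid), int(pat), int(mat)))

    trackable = []
    for r in recs:
        if r.paternal_reads < 0 or r.maternal_reads < 0:
            raise ValueError(f"peak {r.peak_id}: negative read count")
        r.allelic_ratio = allelic_ratio(r.paternal_reads, r.maternal_reads)
        total = r.paternal_reads + r.maternal_reads
        if total < min_reads:
            r.label = "untrackable"
            r.p_value = r.p_adjusted = None
        else:
            r.p_value = binom_exact_two_sided(r.paternal_reads, total)
            trackable.append(r)

    if trackable:
        adjusted = bh_adjust([r.p_value for r in trackable], method=adjust_method)
        for r, padj in zip(trackable, adjusted):
            r.p_adjusted = float(padj)
            if r.allelic_ratio >= ratio_hi and r.p_adjusted < alpha:
                r.label = "paternal"
            elif r.allelic_ratio <= ratio_lo and r.p_adjusted < alpha:
                r.label = "maternal"
            else:
                r.label = "biallelic"

    counts = {lab: 0 for lab in ("paternal", "maternal", "biallelic", "untrackable")}
    for r in recs:
        counts[r.label] += 1
    n_track = len(trackable)
    summary = {
        "counts": counts,
        "n_trackable": n_track,
        "fraction_biallelic_trackable": counts["biallelic"] / n_track if n_track else None,
        "min_reads": min_reads,
        "ratio_hi": ratio_hi,
        "ratio_lo": ratio_lo,
        "alpha": alpha,
        "adjust_method": adjust_method,
    }
    return recs, summary


def records_to_frame(records: Iterable[AllelicPeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.peak_id, r.paternal_reads, r.maternal_reads, r.allelic_ratio,
             r.p_value, r.p_adjusted, r.label)
            for r in records
        ],
        columns=["peak_id", "paternal", "maternal", "allelic_ratio",
                 "p_value", "p_adjusted", "label"],
    )
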