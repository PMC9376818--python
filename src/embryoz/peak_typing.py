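"""Promoter peak-type classification via the K statistic.

A promoter with strong enrichment (RPKM > 1 over TSS ± 1 kb) is "Double" if
both flanking nucleosome windows exceed the TSS window in the product-of-logs
sense (K > 0) and "Single" otherwise (K ≤ 0); weak promoters (RPKM ≤ 1) are
"No".  K multiplies the log2 ratios of the −1- and +1-nucleosome window
means to the TSS window mean:

    K = log2((m−1 + ε) / (t + ε)) · log2((m+1 + ε) / (t + ε))

K is positive when both flanks deviate from the TSS trough in the same
direction.  The same sign also arises when both flanks are *below* the TSS
window (a TSS-centred peak); such promoters keep the literal Double label
but are flagged ``tss_centered``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from embryoz.genome_io import CoverageTrack, GeneRecord
from embryoz.promoter_signal import PromoterSignal, quantify_promoters

LABELS = ("Double", "Single", "No")
DEFAULT_EPS = 0.1  # RPM pseudocount; K is undefined at zero window means
DEFAULT_RPKM_THRESHOLD = 1.0


@dataclass(frozen=True)
class PeakTypeCall:
    gene_id: str
    rpkm_promoter: float
    k_value: Optional[float]  # None iff label == "No"
    label: str
    tss_centered: bool = False


def k_statistic(
    mean_minus1: float, mean_tss: float, mean_plus1: float, eps: float = DEFAULT_EPS
) -> float:
    """K = log2((m+ε)/(t+ε)) × log2((p+ε)/(t+ε)) on the three window means."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min(mean_minus1, mean_tss, mean_plus1) < 0:
        raise ValueError("window means must be nonnegative")
    t = mean_tss + eps
    return math.log2((mean_minus1 + eps) / t) * math.log2((mean_plus1 + eps) / t)


def classify_promoter(
    signal: PromoterSignal,
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD,
    eps: float = DEFAULT_EPS,
) -> PeakTypeCall:
    """Apply the peak-type rule: No if RPKM ≤ threshold, else Double/Single by K."""
    if signal.rpkm_promoter <= rpkm_threshold:
        return PeakTypeCall(signal.gene_id, signal.rpkm_promoter, None, "No")
    k = k_statistic(signal.mean_minus1, signal.mean_tss, signal.mean_plus1, eps)
    label = "Double" if k > 0 else "Single"
    tss_centered = (
        label == "Double"
        and signal.mean_minus1 < signal.mean_tss
        and signal.mean_plus1 < signal.mean_tss
    )
    return PeakTypeCall(signal.gene_id, signal.rpkm_promoter, k, label, tss_centered)


def classify_all(
    track: CoverageTrack,
    genes: Sequence[GeneRecord],
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD,
    eps: float = DEFAULT_EPS,
) -> tuple[list[PeakTypeCall], dict[str, int]]:
    """Classify every gene's promoter on one coverage track.

    Returns the per-gene calls and summary counts per label.
    """
    signals = quantify_promoters(track, genes)
    calls = [classify_promoter(s, rpkm_threshold, eps) for s in signals]
    counts = {label: 0 for label in LABELS}
    for call in calls:
        counts[call.label] += 1
    return calls, counts


def calls_to_frame(calls: Iterable[PeakTypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.gene_id, c.rpkm_promoter, c.k_value, c.label, c.tss_centered)
            for c in calls
        ],
        columns=["gene_id", "rpkm_promoter", "k_value", "label", "tss_centered"],
    )


def quartile_partition(
    rpkm: pd.Series, rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD
) -> pd.Series:
    """Split promoters into No / Low / Medium / High enrichment.

    Promoters at RPKM ≤ threshold are "No"; the rest are split at the
    empirical 1/3 and 2/3 quantiles of their RPKM.
    """
    labels = pd.Series("No", index=rpkm.index, dtype=object)
    enriched = rpkm[rpkm > rpkm_threshold]
    if len(enriched) == 0:
        return labels
    if len(enriched) < 3:
        raise ValueError(f"only {len(enriched)} promoters above threshold; need >= 3")
    ranks = enriched.rank(method="first")
    tertile = np.ceil(ranks * 3 / len(enriched)).astype(int)
    labels.loc[enriched.index] = tertile.map({1: "Low", 2: "Medium", 3: "High"})
    return labels


# ---------------------------------------------------------------------------
# stage-to-stage transitions


@dataclass
class TransitionTable:
    """3×3 peak-type transition counts between two stages.

    ``fractions`` normalizes each (source, target) count by the source-label
    total at stage A, matching the "Double to Single: x% of Double genes"
    convention.
    """

    counts: pd.DataFrame  # index: label at stage A; columns: label at stage B
    fractions: pd.DataFrame
    n_genes: int


def transitions(
    calls_a: Iterable[PeakTypeCall], calls_b: Iterable[PeakTypeCall]
) -> TransitionTable:
    """Tabulate label transitions on the genes present at both stages."""
    a = {c.gene_id: c.label for c in calls_a}
    b = {c.gene_id: c.label for c in calls_b}
    shared = sorted(a.keys() & b.keys())
    if not shared:
        raise ValueError("no shared genes between the two call sets")
    counts = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS), dtype=int)
    for g in shared:
        counts.loc[a[g], b[g]] += 1
    row_totals = counts.sum(axis=1)
    fractions = counts.div(row_totals.replace(0, np.nan), axis=0)
    return TransitionTable(counts=counts, fractions=fractions, n_genes=len(shared))
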