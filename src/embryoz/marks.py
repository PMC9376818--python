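"""Histone-mark state integration.

Four promoter chromatin states from H3K4me3 / H3K27me3 promoter RPKM:
K4only, K27only, Bivalent (both) and Unmarked (neither), each mark "present"
above an RPKM threshold (default 1, the same promoter-enrichment convention
used for peak typing).  Also: the origin of blastocyst (ICM) H3K27me3
(de novo vs inherited from oocytes), Polycomb-target calls from ESC
H3K27me3 peaks near the TSS, expression classes from FPKM, and the
composition of differentially expressed genes by promoter peak type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from embryoz.genome_io import GeneRecord, Interval
from embryoz.dynamics import _build_trees, _any_overlap
from embryoz.peak_typing import PeakTypeCall

MARK_STATES = ("K4only", "K27only", "Bivalent", "Unmarked")
MARK_THRESHOLD = 1.0
ORIGIN_EPS = 0.1


def mark_state(k4_rpkm: float, k27_rpkm: float, threshold: float = MARK_THRESHOLD) -> str:
    """One of K4only / K27only / Bivalent / Unmarked from the two RPKMs."""
    if k4_rpkm < 0 or k27_rpkm < 0:
        raise ValueError("RPKM must be nonnegative")
    k4, k27 = k4_rpkm > threshold, k27_rpkm > threshold
    if k4 and k27:
        return "Bivalent"
    if k4:
        return "K4only"
    if k27:
        return "K27only"
    return "Unmarked"


@dataclass(frozen=True)
class K27OriginCall:
    gene_id: str
    icm_rpkm: float
    mii_rpkm: float
    cleavage_rpkm: float
    ratio: Optional[float]
    origin: Optional[str]  # de_novo / inherited / unclassified; None if not gated in


def k27_origin(
    gene_id: str,
    icm_rpkm: float,
    mii_rpkm: float,
    cleavage2_rpkm: float,
    cleavage8_rpkm: float,
    eps: float = ORIGIN_EPS,
    icm_threshold: float = 1.0,
    low_ratio_means_inherited: bool = True,
) -> K27OriginCall:
    """Classify ICM promoter H3K27me3 as established de novo or inherited.

    Only genes with ICM enrichment above ``icm_threshold`` are considered.
    The ratio is oocyte (MII) enrichment over the mean of the 2-cell and
    8-cell stages, with a pseudocount on both sides.  Ratio > 1 → de novo
    establishment in ICM; ratio < 0.5 → maternal inheritance (the printed
    rule; flip with ``low_ratio_means_inherited=False``); otherwise
    unclassified.
    """
    cleavage = (cleavage2_rpkm + cleavage8_rpkm) / 2.0
    if icm_rpkm <= icm_threshold:
        return K27OriginCall(gene_id, icm_rpkm, mii_rpkm, cleavage, None, None)
    ratio = (mii_rpkm + eps) / (cleavage + eps)
    if ratio > 1:
        origin = "de_novo" if low_ratio_means_inherited else "inherited"
    elif ratio < 0.5:
        origin = "inherited" if low_ratio_means_inherited else "de_novo"
    else:
        origin = "unclassified"
    return K27OriginCall(gene_id, icm_rpkm, mii_rpkm, cleavage, ratio, origin)


def pcg_targets(
    esc_k27_peaks: Sequence[Interval],
    genes: Sequence[GeneRecord],
    half_width: int = 5000,
) -> pd.Series:
    """True per gene iff any ESC H3K27me3 peak overlaps TSS ± 5 kb."""
    trees = _build_trees(esc_k27_peaks)
    flags = {}
    for g in genes:
        window = Interval(g.chrom, max(g.tss - half_width, 0), g.tss + half_width)
        flags[g.gene_id] = _any_overlap(window, trees)
    return pd.Series(flags, name="pcg_target")


def set_enrichment(
    gene_set: Sequence[str],
    target_flags: pd.Series,
    universe: Optional[Sequence[str]] = None,
    n_random: int = 1000,
    seed: int = 0,
) -> dict:
    """Observed/expected enrichment of a flag within a gene set, with a
    same-size random-draw control distribution.

    Observed = fraction of the set flagged; expected = fraction of the
    universe flagged.  ``random_fractions`` holds the observed fraction in
    ``n_random`` same-size draws from the universe.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    universe = list(universe) if universe is not None else list(target_flags.index)
    missing = set(gene_set) - set(universe)
    if missing:
        raise ValueError(f"gene set not within universe: {sorted(missing)[:5]}")
    flags = target_flags.reindex(universe).fillna(False).astype(bool)
    observed = float(flags.loc[list(gene_set)].mean())
    expected = float(flags.mean())
    rng = np.random.default_rng(seed)
    flag_values = flags.to_numpy()
    draws = np.array(
        [
            flag_values[rng.choice(len(universe), size=len(gene_set), replace=False)].mean()
            for _ in range(n_random)
        ]
    )
    return {
        "observed": observed,
        "expected": expected,
        "ratio": observed / expected if expected > 0 else np.inf,
        "random_fractions": draws,
    }


def expression_class(fpkm: float) -> str:
    """active (FPKM > 1) / inactive (FPKM < 0.1) / intermediate."""
    if fpkm < 0:
        raise ValueError("FPKM must be nonnegative")
    if fpkm > 1:
        return "active"
    if fpkm < 0.1:
        return "inactive"
    return "intermediate"


def deg_peaktype_composition(
    deg_table: pd.DataFrame,
    calls: Iterable[PeakTypeCall],
) -> dict:
    """Compose DEG classes with promoter peak types.

    C1 = upregulated DEGs at peak-marked promoters (label ≠ No), C2 =
    downregulated DEGs at marked promoters; nonmarked DEGs are counted
    separately.  Within C1/C2 the Single vs Double split is reported.
    DEGs absent from the call set are dropped with a warning count.
    """
    labels = {c.gene_id: c.label for c in calls}
    report = {"C1": {"n": 0, "Single": 0, "Double": 0},
              "C2": {"n": 0, "Single": 0, "Double": 0},
              "nonmarked": {"up": 0, "down": 0},
              "dropped": 0}
    for row in deg_table.itertuples(index=False):
        gene, direction = str(row.gene_id), str(row.direction)
        if direction not in ("up", "down"):
            raise ValueError(f"DEG direction must be 'up'/'down', got {direction!r}")
        label = labels.get(gene)
        if label is None:
            report["dropped"] += 1
            continue
        if label == "No":
            report["nonmarked"][direction] += 1
            continue
        cls = "C1" if direction == "up" else "C2"
        report[cls]["n"] += 1
        report[cls][label] += 1
    for cls in ("C1", "C2"):
        n = report[cls]["n"]
        report[cls]["single_fraction"] = report[cls]["Single"] / n if n else None
        report[cls]["double_fraction"] = report[cls]["Double"] / n if n else None
    return report
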