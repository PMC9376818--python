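"""Stage-to-stage peak dynamics, genomic feature annotation and enrichment.

"Overlap" is any shared base under half-open interval arithmetic — the
default of the standard interval-intersection tooling.  A peak at one stage
is *gained* if nothing at the previous stage overlaps it, *maintained*
otherwise, and *lost* if nothing at the next stage overlaps it.

Peaks are annotated to exactly one genomic feature with the total priority
promoter > exon > intron > intergenic: the highest-priority feature any
base of the peak touches wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from embryoz.genome_io import CoverageTrack, Interval

FEATURE_PRIORITY = ("promoter", "exon", "intron", "intergenic")


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two intervals share >= 1 base (half-open)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _build_trees(peaks: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def _any_overlap(peak: Interval, trees: Mapping[str, IntervalTree]) -> bool:
    tree = trees.get(peak.chrom)
    return tree is not None and bool(tree.overlap(peak.start, peak.end))


@dataclass
class StageDynamics:
    """Gained / lost / maintained peaks at one stage."""

    gained: list[Interval]
    maintained: list[Interval]
    lost: list[Interval]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "gained": len(self.gained),
            "maintained": len(self.maintained),
            "lost": len(self.lost),
        }


def stage_dynamics(
    prev_peaks: Optional[Sequence[Interval]],
    cur_peaks: Sequence[Interval],
    next_peaks: Optional[Sequence[Interval]],
) -> StageDynamics:
    """Classify the current stage's peaks against its neighbours.

    With no previous stage every current peak is gained; with no next stage
    no peak is lost.  Gained and maintained partition the current peak set.
    """
    prev_trees = _build_trees(prev_peaks or [])
    next_trees = _build_trees(next_peaks or [])
    gained, maintained, lost = [], [], []
    for peak in cur_peaks:
        if _any_overlap(peak, prev_trees):
            maintained.append(peak)
        else:
            gained.append(peak)
        if next_peaks is not None and not _any_overlap(peak, next_trees):
            lost.append(peak)
    return StageDynamics(gained=gained, maintained=maintained, lost=lost)


def stage_series_dynamics(
    stage_peaks: Mapping[str, Sequence[Interval]]
) -> dict[str, StageDynamics]:
    """Run :func:`stage_dynamics` over an ordered stage series."""
    names = list(stage_peaks)
    out = {}
    for i, name in enumerate(names):
        prev = stage_peaks[names[i - 1]] if i > 0 else None
        nxt = stage_peaks[names[i + 1]] if i + 1 < len(names) else None
        out[name] = stage_dynamics(prev, stage_peaks[name], nxt)
    return out


# ---------------------------------------------------------------------------
# feature annotation


@dataclass
class AnnotationModel:
    """Merged promoter/exon/intron footprints with a total feature priority."""

    features: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)
    footprints: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        promoters: Sequence[Interval],
        exons: Sequence[Interval] = (),
        introns: Sequence[Interval] = (),
        extra: Optional[Mapping[str, Sequence[Interval]]] = None,
    ) -> "AnnotationModel":
        """Build from per-feature interval lists; footprints are merged bp.

        ``extra`` prepends additional feature classes (e.g. a repeat track)
        ahead of intergenic in priority.
        """
        model = cls()
        classes: list[tuple[str, Sequence[Interval]]] = [
            ("promoter", promoters),
            ("exon", exons),
            ("intron", introns),
        ]
        if extra:
            classes.extend(extra.items())
        for name, ivs in classes:
            trees = _build_trees(ivs)
            for t in trees.values():
                t.merge_overlaps()
            model.features[name] = trees
            model.footprints[name] = int(
                sum(iv.end - iv.begin for t in trees.values() for iv in t)
            )
        return model

    @property
    def priority(self) -> list[str]:
        return list(self.features) + ["intergenic"]


def annotate_peak(peak: Interval, model: AnnotationModel) -> str:
    """The highest-priority feature any base of the peak overlaps."""
    for name, trees in model.features.items():
        if _any_overlap(peak, trees):
            return name
    return "intergenic"


def obs_exp_enrichment(
    peaks: Sequence[Interval],
    feature: str,
    model: AnnotationModel,
    genome_size: int,
) -> float:
    """Observed/expected enrichment of peaks in one feature class.

    Observed is count-based: the fraction of peaks whose priority annotation
    is the feature.  Expected is the merged feature footprint divided by the
    genome size (intergenic footprint is the complement of all others).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if not peaks:
        raise ValueError("no peaks supplied")
    if feature == "intergenic":
        footprint = genome_size - sum(model.footprints.values())
    else:
        footprint = model.footprints.get(feature, 0)
    if footprint <= 0:
        raise ValueError(f"feature {feature!r} has zero footprint")
    observed = sum(annotate_peak(p, model) == feature for p in peaks) / len(peaks)
    expected = footprint / genome_size
    return observed / expected


# ---------------------------------------------------------------------------
# naive peak calling (synthetic end-to-end runs only)


def naive_peak_caller(
    track: CoverageTrack,
    fold: float = 4.0,
    min_len: int = 150,
    merge_gap: int = 100,
) -> list[Interval]:
    """Threshold peak caller: maximal runs of coverage above fold × the
    genome-wide mean, gap-merged then length-filtered.

    A deliberately simple caller for simulated coverage; it stands in for a
    model-based caller only on synthetic end-to-end runs.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    v = track.values
    mean = v.mean()
    if mean == 0:
        return []
    above = v > fold * mean
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    return [
        Interval(track.chrom, s, e, name=f"peak_{i + 1}")
        for i, (s, e) in enumerate(merged)
        if e - s >= min_len
    ]
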