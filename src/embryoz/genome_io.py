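"""Readers and writers for the text formats the pipeline touches.

Coordinate conventions are fixed package-wide: 0-based, half-open
([start, end)), the BED convention.  The TSS of a minus-strand gene is the
rightmost transcribed base of its annotated span.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

STRANDS = ("+", "-")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates an invariant (coordinates, uniqueness...)."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: the anchor for all promoter windows.

    ``tss`` is the 0-based coordinate of the transcription start base.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-base fragment-pileup signal on one chromosome.

    ``values`` holds raw read-equivalent coverage (fragments overlapping each
    base).  ``library_size`` is the total mapped reads the track derives
    from; per-base RPM is ``values / (library_size / 1e6)``.
    """

    chrom: str
    values: np.ndarray
    library_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.chrom}: coverage values must be nonnegative")
        if self.library_size <= 0:
            raise ValidationError(f"{self.chrom}: library_size must be positive")

    def __len__(self) -> int:
        return self.values.size

    def rpm(self) -> np.ndarray:
        """Per-base signal on the reads-per-million scale."""
        return self.values / (self.library_size / 1e6)


# ---------------------------------------------------------------------------
# gene tables

GENE_COLUMNS = ("gene_id", "chrom", "tss", "strand")


def read_gene_table(path) -> list[GeneRecord]:
    """Read a tab-separated gene table with columns gene_id, chrom, tss, strand.

    Raises :class:`ParseError` naming the offending line and
    :class:`ValidationError` on duplicate gene ids.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records: list[GeneRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            tss = int(getattr(row, "tss"))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{i}: non-integer tss {getattr(row, 'tss')!r}") from exc
        records.append(GeneRecord(str(row.gene_id), str(row.chrom), tss, str(row.strand)))
    ids = [g.gene_id for g in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValidationError(f"{path}: duplicate gene ids {dupes[:5]}")
    return records


def write_gene_table(genes: Iterable[GeneRecord], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes], columns=list(GENE_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval files

_DIALECT_MIN_COLS = {"bed": 3, "narrowPeak": 10, "broadPeak": 9}


def read_intervals(path, dialect: str = "bed") -> list[Interval]:
    """Read a BED / narrowPeak / broadPeak file, preserving file order.

    BED name and score come from columns 4 and 5 when present; for
    narrowPeak/broadPeak the score is the signalValue (column 7).
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < _DIALECT_MIN_COLS[dialect]:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_DIALECT_MIN_COLS[dialect]} columns "
                    f"for {dialect}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if dialect == "bed":
                if len(fields) > 4 and fields[4] != ".":
                    score = float(fields[4])
            else:  # narrowPeak / broadPeak signalValue
                score = float(fields[6])
            out.append(Interval(fields[0], start, end, name=name, score=score))
    return out


def write_intervals(intervals: Iterable[Interval], path) -> None:
    """Write intervals as BED4/5 (name '.' when absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name if iv.name else "."]
            if iv.score is not None:
                cols.append(repr(float(iv.score)))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# chrom sizes & bedGraph coverage

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_bedgraph(
    path,
    chrom_sizes: Mapping[str, int],
    library_size: Optional[float] = None,
) -> dict[str, CoverageTrack]:
    """Read a bedGraph into dense per-base tracks, one per declared chromosome.

    Unspecified bases are 0.  Records must not overlap within a chromosome
    and must not extend past the declared chromosome length.  A leading
    ``# library_size=N`` comment (written by :func:`write_bedgraph`) supplies
    the library size unless overridden by the argument.
    """
    arrays = {c: np.zeros(int(n), dtype=float) for c, n in chrom_sizes.items()}
    seen_end: dict[str, int] = {}
    lib = library_size
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "library_size=" in line and library_size is None:
                    lib = float(line.split("library_size=")[1].split()[0])
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad record") from exc
            if chrom not in arrays:
                raise ValidationError(f"{path}:{lineno}: undeclared chromosome {chrom!r}")
            if end > arrays[chrom].size:
                raise ValidationError(
                    f"{path}:{lineno}: record end {end} beyond chromosome length "
                    f"{arrays[chrom].size}"
                )
            if start < seen_end.get(chrom, 0):
                raise ValidationError(f"{path}:{lineno}: overlapping or unsorted records")
            seen_end[chrom] = end
            arrays[chrom][start:end] = value
    if lib is None:
        # fall back: treat total signal as read-equivalents of 150-bp fragments
        total = sum(a.sum() for a in arrays.values())
        lib = max(total / 150.0, 1.0)
    return {c: CoverageTrack(c, a, lib) for c, a in arrays.items()}


def write_bedgraph(tracks: Union[CoverageTrack, Iterable[CoverageTrack]], path) -> None:
    """Write tracks as bedGraph, run-length encoding equal adjacent values.

    Zero runs are omitted; a ``# library_size=`` comment preserves the
    normalization constant for exact round-trips.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    tracks = list(tracks)
    with open(path, "w") as fh:
        if tracks:
            fh.write(f"# library_size={float(tracks[0].library_size)!r}\n")
        for track in tracks:
            v = track.values
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{track.chrom}\t{s}\t{e}\t{float(v[s])!r}\n")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers over Biopython)

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
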