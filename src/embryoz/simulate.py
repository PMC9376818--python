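"""Synthetic early-embryo ChIP-seq generator with planted truth.

The generator emulates the statistical structure of ultra-low-input native
ChIP-seq of promoter nucleosomes in early embryos: mononucleosomal 150-bp
fragments whose midpoints cluster at the −1/+1 nucleosome positions flanking
each TSS.  Three promoter architectures are planted — "Double" (equal
mixture at TSS ± offset, strand-oriented), "Single" (+1 nucleosome only) and
"No" (background only) — along with per-peak parent-of-origin read classes,
H3K4me3/H3K27me3 mark states coupled to the architecture, and FPKM values
whose class means separate active (> 1) from inactive (< 0.1) genes.

Everything is seeded: a fixed config yields byte-identical outputs.  Each
sub-simulation draws from its own stream derived from the config seed, so
individual operations are reproducible regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from embryoz.genome_io import CoverageTrack, GeneRecord, Interval

ARCHITECTURES = ("Double", "Single", "No")
MARK_STATES = ("K4only", "K27only", "Bivalent", "Unmarked")
EXPRESSION_CLASSES = ("active", "inactive", "intermediate")
ALLELIC_CLASSES = ("biallelic", "biased_pat", "biased_mat")

# stream ids so each sub-simulation has an independent, stable RNG
_STREAMS = {"annotation": 1, "sequence": 2, "truth": 3, "h2az": 4,
            "allelic": 5, "marks": 6, "expression": 7, "stages": 8}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic embryo dataset.

    ``depth`` is the expected number of ChIP fragments per enriched
    promoter; ``background_rate`` is fragments per kb genome-wide.
    ``library_size`` is the genome-wide mapped-read count the simulated
    chromosome is notionally an excerpt of; it sets the RPM/RPKM scale.
    """

    n_genes: int = 1000
    chrom: str = "chrS"
    chrom_length: Optional[int] = None  # default: 12 kb spacing per gene
    seed: int = 0
    depth: float = 200.0
    background_rate: float = 5.0  # fragments per kb
    fragment_length: int = 150
    nucleosome_offset: int = 180
    nucleosome_sd: float = 50.0
    library_size: float = 20e6
    type_proportions: dict = field(
        default_factory=lambda: {"Double": 0.4, "Single": 0.3, "No": 0.3}
    )
    bivalent_given_single: float = 0.30
    bivalent_leak_double: float = 0.05
    allelic_class_proportions: dict = field(
        default_factory=lambda: {"biallelic": 0.87, "biased_pat": 0.08, "biased_mat": 0.05}
    )
    paternal_fraction: dict = field(
        default_factory=lambda: {"biased_pat": 0.95, "biased_mat": 0.05, "biallelic": 0.5}
    )
    snp_trackable_probability: float = 0.5
    cpg_density: dict = field(
        default_factory=lambda: {"Double": 0.06, "Single": 0.02, "No": 0.005}
    )  # CpGs per promoter base
    stage: str = "morula"

    def __post_init__(self) -> None:
        if self.chrom_length is None:
            self.chrom_length = 12_000 * (self.n_genes + 1)
        for name, props in (("type_proportions", self.type_proportions),
                            ("allelic_class_proportions", self.allelic_class_proportions)):
            total = sum(props.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigurationError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in props.values()):
                raise ConfigurationError(f"{name} must be nonnegative")
        for val, name in ((self.depth, "depth"), (self.background_rate, "background_rate"),
                          (self.nucleosome_sd, "nucleosome_sd")):
            if val < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_genes > 0:
            spacing = self.chrom_length // (self.n_genes + 1)
            if spacing < 10_500:
                raise ConfigurationError(
                    f"chromosome too small: {self.n_genes} genes need >= "
                    f"{10_500 * (self.n_genes + 1)} bp, got {self.chrom_length}"
                )

    def rng(self, stream: str, index: int = 0) -> np.random.Generator:
        """An independent, reproducible stream per sub-simulation (and per
        stage replicate via ``index``)."""
        return np.random.default_rng([_STREAMS[stream], index, self.seed])


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene ground truth used by recovery tests."""

    gene_id: str
    architecture: str
    allelic_class: str
    paternal_fraction: float
    mark_state: str
    expression_class: str
    stage: str


def _choice(rng: np.random.Generator, props: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(props)
    return rng.choice(keys, size=n, p=[props[k] for k in keys])


# conditional class structure coupling marks/expression to the architecture
_MARK_GIVEN_ARCH = {
    "Double": {"K4only": 0.85, "Bivalent": None, "Unmarked": None},  # filled from config
    "Single": {"K4only": 0.40, "Bivalent": None, "K27only": 0.10, "Unmarked": None},
    "No": {"K27only": 0.25, "Unmarked": 0.75},
}
_EXPR_GIVEN_ARCH = {
    "Double": {"active": 0.80, "intermediate": 0.15, "inactive": 0.05},
    "Single": {"active": 0.30, "intermediate": 0.40, "inactive": 0.30},
    "No": {"active": 0.10, "intermediate": 0.20, "inactive": 0.70},
}
# log-normal FPKM parameters per expression class (mean log, sd log)
_FPKM_PARAMS = {"active": (math.log(20.0), 0.8),
                "inactive": (math.log(0.01), 0.8),
                "intermediate": (math.log(0.32), 0.5)}


def _mark_distribution(arch: str, config: SimulationConfig) -> dict[str, float]:
    if arch == "Double":
        biv = config.bivalent_leak_double
        return {"K4only": 0.85, "Bivalent": biv, "Unmarked": 0.15 - biv}
    if arch == "Single":
        biv = config.bivalent_given_single
        rest = 1.0 - biv - 0.10 - 0.40
        return {"K4only": 0.40, "Bivalent": biv, "K27only": 0.10, "Unmarked": rest}
    return dict(_MARK_GIVEN_ARCH["No"])


def plant_truth(config: SimulationConfig) -> list[SyntheticTruth]:
    """Assign architecture, allelic class, mark state and expression class."""
    rng = config.rng("truth")
    n = config.n_genes
    archs = _choice(rng, config.type_proportions, n)
    allelic = _choice(rng, config.allelic_class_proportions, n)
    out = []
    for i in range(n):
        arch = str(archs[i])
        mark = str(_choice(rng, _mark_distribution(arch, config), 1)[0])
        expr = str(_choice(rng, _EXPR_GIVEN_ARCH[arch], 1)[0])
        out.append(
            SyntheticTruth(
                gene_id=f"g{i + 1:05d}",
                architecture=arch,
                allelic_class=str(allelic[i]),
                paternal_fraction=float(config.paternal_fraction[str(allelic[i])]),
                mark_state=mark,
                expression_class=expr,
                stage=config.stage,
            )
        )
    return out


def truth_to_frame(truth: Sequence[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truth])


# ---------------------------------------------------------------------------
# annotation + sequence


def simulate_annotation(
    config: SimulationConfig, truth: Optional[Sequence[SyntheticTruth]] = None,
    with_sequence: bool = True,
) -> tuple[list[GeneRecord], Optional[str]]:
    """Evenly spaced, jittered TSSs on one chromosome, plus a sequence whose
    promoter CpG density depends on the planted architecture.

    TSSs are spaced so TSS ± 5 kb never crosses a chromosome end.  When
    ``truth`` is omitted the sequence uses the "No" CpG density everywhere.
    """
    rng = config.rng("annotation")
    n, length = config.n_genes, config.chrom_length
    genes: list[GeneRecord] = []
    if n > 0:
        spacing = length // (n + 1)
        jitter = rng.integers(-spacing // 10, spacing // 10 + 1, size=n)
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            tss = int((i + 1) * spacing + jitter[i])
            genes.append(GeneRecord(f"g{i + 1:05d}", config.chrom, tss, str(strands[i])))
    seq = None
    if with_sequence:
        seq = _simulate_sequence(config, genes, truth)
    return genes, seq


def _simulate_sequence(
    config: SimulationConfig,
    genes: Sequence[GeneRecord],
    truth: Optional[Sequence[SyntheticTruth]],
) -> str:
    rng = config.rng("sequence")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    arr = bases[rng.choice(4, size=config.chrom_length, p=[0.3, 0.2, 0.2, 0.3])].copy()
    # deplete background CpGs (mammalian genomes run at ~20% of expectation)
    cg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
    broken = cg[rng.random(cg.size) < 0.8]
    arr[broken + 1] = b"A"
    arch_by_gene = {t.gene_id: t.architecture for t in truth} if truth else {}
    for gene in genes:
        arch = arch_by_gene.get(gene.gene_id, "No")
        density = config.cpg_density.get(arch, 0.005)
        lo, hi = max(gene.tss - 1000, 0), min(gene.tss + 1000, config.chrom_length)
        n_cpg = rng.poisson(density * (hi - lo))
        if n_cpg == 0:
            continue
        pos = rng.integers(lo, hi - 1, size=n_cpg)
        arr[pos] = b"C"
        arr[pos + 1] = b"G"
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# ChIP fragment placement


def _pileup(midpoints: np.ndarray, frag_len: int, length: int) -> np.ndarray:
    half = frag_len // 2
    starts = np.clip(midpoints - half, 0, length)
    ends = np.clip(midpoints - half + frag_len, 0, length)
    diff = np.zeros(length + 1)
    np.add.at(diff, starts, 1.0)
    np.subtract.at(diff, ends, 1.0)
    return np.cumsum(diff[:length])


def _promoter_midpoints(
    rng: np.random.Generator,
    gene: GeneRecord,
    architecture: str,
    config: SimulationConfig,
    depth: Optional[float] = None,
) -> np.ndarray:
    """Fragment midpoints for one enriched promoter, strand-oriented."""
    depth = config.depth if depth is None else depth
    n = rng.poisson(depth)
    if n == 0:
        return np.empty(0, dtype=int)
    sign = 1 if gene.strand == "+" else -1
    if architecture == "Double":
        comp = rng.choice([-1, 1], size=n)
    elif architecture == "Single":
        comp = np.ones(n, dtype=int)  # +1 nucleosome only
    else:
        return np.empty(0, dtype=int)
    mids = gene.tss + sign * comp * config.nucleosome_offset + rng.normal(
        0.0, config.nucleosome_sd, size=n
    )
    return np.clip(np.rint(mids).astype(int), 0, config.chrom_length - 1)


def truth_peaks(
    genes: Sequence[GeneRecord], truth: Sequence[SyntheticTruth], half_width: int = 500
) -> list[Interval]:
    """Truth-derived peak intervals: TSS ± half_width at enriched promoters."""
    arch = {t.gene_id: t.architecture for t in truth}
    return [
        Interval(g.chrom, g.tss - half_width, g.tss + half_width, name=g.gene_id)
        for g in genes
        if arch[g.gene_id] != "No"
    ]


def simulate_h2az(
    genes: Sequence[GeneRecord],
    truth: Sequence[SyntheticTruth],
    config: SimulationConfig,
    stream_index: int = 0,
) -> tuple[CoverageTrack, list[Interval], pd.DataFrame]:
    """Simulate the H2A.Z coverage track, truth-derived peaks and fragments.

    Double promoters draw fragment midpoints from an equal two-component
    normal mixture at TSS ± offset (strand-oriented); Single promoters from
    the +1 component only; No promoters contribute nothing.  Background
    fragments fall uniformly at ``background_rate`` per kb.  The coverage is
    the 150-bp fragment pileup.
    """
    rng = config.rng("h2az", stream_index)
    arch = {t.gene_id: t.architecture for t in truth}
    mids: list[np.ndarray] = []
    sources: list[np.ndarray] = []
    for gene in genes:
        m = _promoter_midpoints(rng, gene, arch[gene.gene_id], config)
        if m.size:
            mids.append(m)
            sources.append(np.repeat(gene.gene_id, m.size))
    n_bg = rng.poisson(config.background_rate * config.chrom_length / 1000.0)
    if n_bg:
        mids.append(rng.integers(0, config.chrom_length, size=n_bg))
        sources.append(np.repeat("background", n_bg))
    all_mids = np.concatenate(mids) if mids else np.empty(0, dtype=int)
    all_src = np.concatenate(sources) if sources else np.empty(0, dtype=object)
    values = _pileup(all_mids.astype(int), config.fragment_length, config.chrom_length)
    track = CoverageTrack(config.chrom, values, config.library_size)
    fragments = pd.DataFrame({"midpoint": all_mids.astype(int), "source": all_src})
    return track, truth_peaks(genes, truth), fragments


# ---------------------------------------------------------------------------
# allele counts


def simulate_allele_counts(
    peaks: Sequence[Interval],
    truth: Sequence[SyntheticTruth],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-peak paternal/maternal SNP-trackable read counts.

    Total fragments per peak follow the depth model; the trackable subset is
    binomial with ``snp_trackable_probability`` and the paternal count is
    binomial in the planted paternal fraction of the peak's class.
    """
    rng = config.rng("allelic")
    by_gene = {t.gene_id: t for t in truth}
    rows = []
    for peak in peaks:
        t = by_gene.get(peak.name)
        if t is None:
            raise ValueError(f"peak {peak.name!r} has no planted truth")
        n = rng.poisson(config.depth)
        m = rng.binomial(n, config.snp_trackable_probability) if n else 0
        pat = rng.binomial(m, t.paternal_fraction) if m else 0
        rows.append((peak.name, pat, m - pat, t.allelic_class))
    return pd.DataFrame(rows, columns=["peak_id", "paternal", "maternal", "true_class"])


# ---------------------------------------------------------------------------
# marks + expression


def simulate_marks_expression(
    genes: Sequence[GeneRecord],
    truth: Sequence[SyntheticTruth],
    config: SimulationConfig,
) -> tuple[CoverageTrack, CoverageTrack, pd.DataFrame]:
    """H3K4me3 and H3K27me3 tracks plus an FPKM table.

    K4 mirrors the promoter architecture at K4-marked promoters; K27 adds a
    broad domain over TSS ± 500 at Bivalent/K27only promoters.  FPKM is
    log-normal with class parameters separating active (> 1) from inactive
    (< 0.1) genes with probability ≥ 0.99.
    """
    rng = config.rng("marks")
    by_gene = {t.gene_id: t for t in truth}
    k4_mids, k27_mids = [], []
    for gene in genes:
        t = by_gene[gene.gene_id]
        if t.mark_state in ("K4only", "Bivalent"):
            geometry = t.architecture if t.architecture != "No" else "Single"
            m = _promoter_midpoints(rng, gene, geometry, config)
            if m.size:
                k4_mids.append(m)
        if t.mark_state in ("K27only", "Bivalent"):
            n = rng.poisson(config.depth)
            if n:
                k27_mids.append(rng.integers(gene.tss - 500, gene.tss + 500, size=n))
    for mids in (k4_mids, k27_mids):
        n_bg = rng.poisson(config.background_rate * config.chrom_length / 1000.0)
        if n_bg:
            mids.append(rng.integers(0, config.chrom_length, size=n_bg))
    k4 = _pileup(np.concatenate(k4_mids).astype(int) if k4_mids else np.empty(0, int),
                 config.fragment_length, config.chrom_length)
    k27 = _pileup(np.concatenate(k27_mids).astype(int) if k27_mids else np.empty(0, int),
                  config.fragment_length, config.chrom_length)

    expr_rng = config.rng("expression")
    fpkm_rows = []
    for t in truth:
        mu, sd = _FPKM_PARAMS[t.expression_class]
        fpkm_rows.append((t.gene_id, float(np.exp(expr_rng.normal(mu, sd)))))
    fpkm = pd.DataFrame(fpkm_rows, columns=["gene_id", "fpkm"])
    return (
        CoverageTrack(config.chrom, k4, config.library_size),
        CoverageTrack(config.chrom, k27, config.library_size),
        fpkm,
    )


# ---------------------------------------------------------------------------
# stage series + full dataset


def simulate_stage_series(
    config: SimulationConfig,
    stages: Sequence[str] = ("2cell", "8cell", "morula", "blastocyst"),
    persistence: float = 0.7,
) -> dict[str, list[SyntheticTruth]]:
    """Per-stage planted truths where each gene's architecture persists with
    probability ``persistence`` and is otherwise redrawn."""
    rng = config.rng("stages")
    base = plant_truth(config)
    series: dict[str, list[SyntheticTruth]] = {}
    prev = base
    for si, stage in enumerate(stages):
        cur: list[SyntheticTruth] = []
        for t in prev:
            if si == 0 or rng.random() < persistence:
                arch = t.architecture
            else:
                arch = str(_choice(rng, config.type_proportions, 1)[0])
            cur.append(
                SyntheticTruth(t.gene_id, arch, t.allelic_class, t.paternal_fraction,
                               t.mark_state, t.expression_class, stage)
            )
        series[stage] = cur
        prev = cur
    return series


def simulate_deg_table(
    truth: Sequence[SyntheticTruth],
    config: SimulationConfig,
    n_up: int = 100,
    n_down: int = 100,
    p_preferred: float = 0.8,
) -> pd.DataFrame:
    """A synthetic differential-expression gene table.

    Upregulated genes are drawn from Single-architecture promoters with
    probability ``p_preferred`` (otherwise from the rest); downregulated
    genes likewise from Double-architecture promoters.  Mimics a knockdown
    contrast where induced genes sit at +1-only promoters.
    """
    rng = config.rng("truth", index=99)
    singles = [t.gene_id for t in truth if t.architecture == "Single"]
    doubles = [t.gene_id for t in truth if t.architecture == "Double"]
    all_ids = [t.gene_id for t in truth]
    rows = []
    chosen: set[str] = set()

    def draw(preferred: list[str], k: int, direction: str) -> None:
        for _ in range(k):
            pool = preferred if (preferred and rng.random() < p_preferred) else all_ids
            candidates = [g for g in pool if g not in chosen] or [
                g for g in all_ids if g not in chosen
            ]
            if not candidates:
                return
            g = str(rng.choice(candidates))
            chosen.add(g)
            rows.append((g, direction))

    draw(singles, n_up, "up")
    draw(doubles, n_down, "down")
    return pd.DataFrame(rows, columns=["gene_id", "direction"])


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneRecord]
    sequence: Optional[str]
    truth: list[SyntheticTruth]
    h2az: CoverageTrack
    peaks: list[Interval]
    fragments: pd.DataFrame
    allele_counts: pd.DataFrame
    k4: CoverageTrack
    k27: CoverageTrack
    fpkm: pd.DataFrame


def simulate_dataset(config: SimulationConfig, with_sequence: bool = False) -> SyntheticDataset:
    """Generate the full bundle: annotation, H2A.Z, allele counts, marks, FPKM."""
    truth = plant_truth(config)
    genes, seq = simulate_annotation(config, truth, with_sequence=with_sequence)
    h2az, peaks, fragments = simulate_h2az(genes, truth, config)
    allele_counts = simulate_allele_counts(peaks, truth, config)
    k4, k27, fpkm = simulate_marks_expression(genes, truth, config)
    return SyntheticDataset(config, genes, seq, truth, h2az, peaks, fragments,
                            allele_counts, k4, k27, fpkm)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the bundle as plain-text files (TSV / FASTA / bedGraph / BED)."""
    import os

    from embryoz import genome_io

    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)  # noqa: E731
    genome_io.write_gene_table(ds.genes, join("genes.tsv"))
    with open(join("chrom.sizes"), "w") as fh:
        fh.write(f"{ds.config.chrom}\t{ds.config.chrom_length}\n")
    if ds.sequence is not None:
        genome_io.write_fasta({ds.config.chrom: ds.sequence}, join("genome.fa"))
    genome_io.write_bedgraph(ds.h2az, join("h2az.bedgraph"))
    genome_io.write_bedgraph(ds.k4, join("h3k4me3.bedgraph"))
    genome_io.write_bedgraph(ds.k27, join("h3k27me3.bedgraph"))
    genome_io.write_intervals(ds.peaks, join("peaks.bed"))
    ds.allele_counts.to_csv(join("allele_counts.tsv"), sep="\t", index=False)
    ds.fpkm.to_csv(join("fpkm.tsv"), sep="\t", index=False)
    truth_to_frame(ds.truth).to_csv(join("truth.tsv"), sep="\t", index=False)
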