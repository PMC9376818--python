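# embryoz

Promoter H2A.Z peak typing, allele-specific bias and chromatin-state
dynamics for early-embryo ChIP-seq.

## The problem

The histone variant H2A.Z occupies the −1 and +1 nucleosomes flanking
transcription start sites, and the *geometry* of that occupancy — two
flanking peaks around a nucleosome-depleted TSS, a single +1-side peak, or
no enrichment at all — tracks promoter regulatory state across early
embryonic development. Analysing this with ultra-low-input native ChIP-seq
raises several recurring computational tasks:

- quantify ChIP signal in strand-oriented windows around each TSS and
  classify every promoter into **Double / Single / No** peak types;
- test peaks for parent-of-origin (paternal vs maternal) read bias;
- track which peaks are **gained / lost / maintained** between
  developmental stages, and how promoter types transition;
- integrate H3K4me3/H3K27me3 states (bivalency), Polycomb-target status and
  expression classes with the peak types.

`embryoz` implements this pipeline as a tested, reusable library plus CLI,
together with a fully seeded synthetic early-embryo data generator with
planted ground truth, so every stage can be validated end to end without
sequencing data.

## The core statistic

For each gene, mean per-base RPM coverage is computed in three
strand-oriented windows around the TSS: the −1 nucleosome (offsets
−500..−100), the TSS (−20..+20) and the +1 nucleosome (+100..+500). With a
pseudocount ε (default 0.1 RPM):

```
K = log2((m₋₁ + ε) / (m_TSS + ε)) · log2((m₊₁ + ε) / (m_TSS + ε))
```

Promoters with RPKM ≤ 1 over TSS ± 1 kb are **No** type; enriched promoters
are **Double** when K > 0 (both flanks deviate from the TSS trough in the
same direction) and **Single** when K ≤ 0. Allelic bias uses the exact
two-sided binomial test on paternal/maternal read counts per peak (null
p = 0.5), Benjamini–Hochberg adjustment over the trackable family (≥ 10
SNP-trackable reads), and the joint rule: paternal if allelic ratio ≥ 0.85
with adjusted P < 0.05, maternal if ratio ≤ 0.15 with adjusted P < 0.05.

## Worked example

```python
from embryoz.simulate import SimulationConfig, simulate_dataset
from embryoz.peak_typing import classify_all

ds = simulate_dataset(SimulationConfig(n_genes=1000, seed=7))
calls, counts = classify_all(ds.h2az, ds.genes)
print(counts)

truth = {t.gene_id: t.architecture for t in ds.truth}
acc = sum(truth[c.gene_id] == c.label for c in calls) / len(calls)
print(f"planted-architecture recovery: {acc:.3f}")
```

prints

```
{'Double': 397, 'Single': 311, 'No': 292}
planted-architecture recovery: 0.996
```

i.e. of 1000 simulated promoters (40% planted Double, 30% Single, 30% No at
sequencing depth 200 fragments per enriched promoter), the classifier
recovers 99.6% of the planted architectures; the label counts are the
recovered class sizes.

The same pipeline is available from the shell:

```
embryoz demo --seed 7 --out demo_out/        # one-command end-to-end run
embryoz classify --coverage h2az.bedgraph --chrom-sizes chrom.sizes \
    --genes genes.tsv --out calls.tsv
embryoz allelic --counts allele_counts.tsv --out allelic.tsv
```

`demo` writes the full bundle (gene table, FASTA, bedGraph tracks, peak
BED, per-stage dynamics, allelic and mark-state tables) plus a
`summary.json` containing the planted-vs-recovered confusion matrix and
every threshold used.

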