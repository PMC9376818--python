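# Methods

## Coordinate and signal conventions

All coordinates are 0-based, half-open (BED convention). The TSS of a
minus-strand gene is the rightmost transcribed base of its annotated span.
Coverage tracks store raw fragment-pileup counts per base together with the
library size (total mapped reads); RPM is pileup / (library / 10⁶) and
window RPKM recovers read-equivalents as base-coverage sum / fragment
length (150 bp assumed, mononucleosomal). Defining RPKM through
read-equivalents makes it invariant to how the same coverage is binned on
disk.

## Promoter windows and the K statistic

Promoter enrichment is RPKM over TSS ± 1 kb (the span is symmetric and
strand-independent). The three metaprofile windows are strand-oriented and
integerized half-open as [−500, −100), [−20, +21) and [+100, +501), with
offset 0 at the TSS base; for a minus-strand gene the −1 window therefore
lies at genomic [tss+101, tss+501). The printed window bounds are treated
as inclusive, which fixes the one-base integerization once.

K multiplies the two log₂ ratios of flank-window means to the TSS-window
mean, each side receiving a pseudocount ε. ε defaults to 0.1 RPM: K is
undefined at zero means, and 0.1 RPM sits well below single-nucleosome
occupancy at any realistic library size, so only promoters already near the
No boundary are affected. ε is a configuration knob and is echoed into
output metadata.

Classification: RPKM ≤ 1 → No; K > 0 → Double; K ≤ 0 → Single (the
boundary K = 0 is Single by the ≤ rule). K > 0 also arises when *both*
flanks fall below the TSS window — a TSS-centred peak that the Double label
misdescribes. The formula is applied literally, and such promoters carry an
additional `tss_centered` flag rather than a different label.

Enriched promoters can alternatively be partitioned into Low/Medium/High
tertiles at the empirical 1/3 and 2/3 quantiles (rank-based, so tertile
sizes differ by at most one); the quantile convention at ties is the
empirical one.

## Stage dynamics, annotation and enrichment

Peak overlap is any shared base under half-open arithmetic. A stage's peak
is gained if no previous-stage peak overlaps it, maintained otherwise, and
lost if no next-stage peak overlaps it; with no previous stage everything
is gained. Type transitions between stages are tabulated on the gene
intersection, and transition fractions are normalized per *source* label
(the "Double → Single as a fraction of Double" reading); this is
configurable in principle but is the convention reported.

Peaks are annotated to exactly one feature by the total priority
promoter > exon > intron > intergenic — the highest-priority feature any
base touches. Observed/expected enrichment is count-based (each peak
contributes once through its priority annotation) over the merged feature
footprint divided by genome size; a base-pair-based observed fraction would
be a reasonable alternative, and the count-based choice is recorded here as
the default. Under uniform placement of point peaks the expected enrichment
of every class is exactly 1, which the tests verify by simulation.

The included threshold peak caller (runs above fold × genome-wide mean,
gap-merged, length-filtered) exists to close the loop on synthetic data
only; it makes no claim to model-based peak calling on real libraries.

## Allelic bias

The exact two-sided binomial p-value is the total probability of outcomes
no more likely than the observed count under Binomial(n, 0.5) (the minlike
convention; at p₀ = 0.5 it equals the doubled symmetric tail capped at 1).
Peaks with fewer than 10 SNP-trackable reads are untrackable and excluded
*before* adjustment, so the multiple-testing family is the trackable set.
Adjustment is Benjamini–Hochberg by default (the correction method is a
knob, Bonferroni available, and is echoed in the summary). Ratio gates are
inclusive: ≥ 0.85 paternal, ≤ 0.15 maternal, both requiring adjusted
P < 0.05; everything else trackable is biallelic.

## Mark states, K27 origin, expression

A promoter is "marked" by H3K4me3 or H3K27me3 when its promoter RPKM
exceeds 1, the same enrichment convention as peak typing; both marks →
Bivalent, neither → Unmarked. The threshold (and a peak-overlap mode) is
configurable since a mark-calling rule can reasonably be defined either
way.

The origin of ICM H3K27me3 is gated on ICM promoter RPKM > 1, then
classified by the ratio of MII-oocyte enrichment to the mean of the 2-cell
and 8-cell stages (pseudocount 0.1 on both sides): ratio > 1 → de novo,
ratio < 0.5 → inherited, else unclassified. The mean was chosen as the
cleavage denominator over min/max/both-stage alternatives as the least
committal reading of "2-cell/8-cell". The low-ratio → inherited direction
is counterintuitive (a mark inherited from oocytes is usually *higher* in
oocytes); the literal rule is implemented and a switch
(`low_ratio_means_inherited`) flips it without guessing intent.

Polycomb targets are genes with any ESC H3K27me3 peak overlapping
TSS ± 5 kb. Gene-set enrichment reports observed/expected flag fractions
plus the empirical distribution over same-size random draws. Expression
classes: FPKM > 1 active, < 0.1 inactive, else intermediate. DEG
composition: C1 = upregulated DEGs at marked (non-No) promoters, C2 =
downregulated, with the Single/Double split inside each.

## The synthetic embryo generator

The generator emulates ULI-NChIP-style mononucleosomal data: 150-bp
fragments, midpoint-anchored, with promoter fragments drawn from normal
components at TSS ± offset (offset 180 bp, sd 50 bp — centring the ±1
components inside the −500..−100 and +100..+500 windows), equal mixture for
Double, +1-only for Single, background-only for No. Background fragments
fall uniformly at 5 fragments/kb. Default conditions: 1000 genes on one
12-Mb chromosome (12-kb spacing with ±10% jitter keeps every TSS ± 5 kb
window on-chromosome), depth 200 fragments per enriched promoter, type
proportions 0.4/0.3/0.3.

The simulated chromosome is an *excerpt* of a genome, so tracks are
normalized against a configured genome-wide library size (default 2 × 10⁷
mapped reads, the scale of a typical low-input ChIP library) rather than
the simulated fragment count; promoter-RPKM thresholds of 1 presuppose
genome-scale normalization. At these settings an enriched promoter sits at
RPKM ≈ 5 and a background promoter at ≈ 0.3, so the No threshold separates
cleanly at depth 200 and degrades gracefully at depth 50.

Truth peaks are emitted directly as TSS ± 500 of enriched genes, so the
allelic and dynamics stages are testable independently of the naive caller.
Allele counts per peak: total ~ Poisson(depth), trackable ~ Binomial(total,
0.5), paternal ~ Binomial(trackable, class fraction) with planted classes
87% biallelic (0.5), 8% paternal-biased (0.95), 5% maternal-biased (0.05).
Mark states couple to architecture (bivalency arises at Single promoters
with probability 0.3 plus a 0.05 leak to Double; No promoters are never
bivalent); K4 coverage mirrors the H2A.Z geometry, K27 adds a broad
TSS ± 500 domain. FPKM is log-normal per class (log-means ln 20, ln 0.32,
ln 0.01; sds 0.8/0.5/0.8), separating active (> 1) from inactive (< 0.1)
with probability ≥ 0.99. Promoter CpG density follows architecture
(0.06/0.02/0.005 planted CpG per base over a background depleted to ~20% of
the random expectation, mimicking mammalian CpG suppression and
CpG-island-like Double promoters).

Every sub-simulation draws from its own RNG stream derived from the config
seed, so a fixed config yields byte-identical files and each stage is
independently reproducible. Stage series redraw each gene's architecture
with persistence 0.7 per stage transition.

What the generator does *not* emulate: read-level error and mappability,
fragment-length variation, diploid sequence and SNP placement (allele
counts are planted downstream of trackability), copy-number or batch
effects, and correlated noise between neighbouring promoters. Passing
recovery tests therefore demonstrates correctness of the statistics and the
pipeline plumbing under the stated generative model, not robustness to
every artefact of real libraries.

## Numerical choices and problem sizes

- Exact binomial p-values come from `scipy.stats.binomtest`
  (cross-checked in tests against full pmf enumeration for n ≤ 25);
  BH from `statsmodels`; k-means from scikit-learn (Lloyd, 10 restarts,
  seeded); hierarchical clustering is average linkage on 1 − Pearson r.
- Z-scores use the population (n) standard deviation — normalization, not
  inference — and zero-variance columns are an error naming the sample.
- CpG counting is forward-strand only (a CpG is its own reverse complement
  at the dinucleotide level); N never matches.
- Genome binning keeps the final partial bin, normalized by its true
  length, so read-equivalents are conserved.
- The test suite and the acceptance script run the generator at 1000 genes
  (300 for the end-to-end demo), 5-seed sweeps for recovery, 2000
  replicates for the enrichment null and the allelic global null — sizes at
  which every Monte-Carlo tolerance used (3 SE, 1 pp monotonicity slack)
  is comfortably resolved on a single CPU in a few seconds.

## Known limitations

- The literal K > 0 rule conflates double-flank and TSS-centred geometries;
  the `tss_centered` flag is a patch, not a third class.
- The naive peak caller has no local background model; do not use it on
  real data.
- Transition-fraction and observed-probability conventions (per-source
  normalization; count-based observed) are defensible readings of
  under-specified conventions and are kept configurable where they matter.
- Real-data replication (alignment, model-based peak calling, SNP-split
  allele assignment, DEG calling) is upstream of this package and out of
  scope; those outputs are consumed as inputs.
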