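# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention), including
the gene table, so conversions happen only at I/O edges. Chromosome names
are compared as exact strings — no `chr` aliasing, so a naming mismatch
between inputs fails loudly instead of silently dropping data. Coverage is
exchanged as 4-column bedGraph (a stand-in for binary bigWig); values are
treated as depth-normalized per-bp rates, and a `SignalTrack` answers mean
and integral queries over arbitrary intervals in O(log n) via a cumulative
integral, with uncovered positions counting as zero. narrowPeak column 10
supplies the summit; −1 or BED6 input falls back to the interval midpoint,
and a summit outside its interval is rejected rather than clamped.

## Signal matrices and clustering

Matrices are anchored at peak summits (±2,000 bp default) or gene TSSs
(±5,000 bp default) with 50-bp bins (the bin width is a package choice; it
is small relative to the 150-bp bump scale of the signal being profiled).
Bin values are mean coverage over the bin; bins reaching past the
chromosome start are zero-filled; minus-strand TSS anchors reverse bin
order so upstream is always left. Condition contrasts use
log2((a + c)/(b + c)) with pseudocount c = 1.0 on depth-normalized values,
bounding log-ratios at empty bins.

k-means uses k-means++ initialization, best of 10 restarts by
within-cluster sum of squares, with a mandatory seed, so results are
bit-reproducible. Because k-means labels are arbitrary permutations,
clusters are relabeled by descending mean matrix value: "cluster 1" is
always the strongest, which makes downstream tables and tests stable. The
knockdown contrast is clustered on the difference matrix
(log2(KD/Control)); clustering concatenated condition matrices is possible
through the same API but the difference matrix is what the planted-class
recovery targets.

## Peak annotation

Classification is by summit position with precedence promoter > exon >
intron > downstream > distal intergenic. The promoter window is
−2,000/+500 bp around the TSS in transcription direction, and `downstream`
extends 3,000 bp past the gene end; both are configurable — these are
declared conventions, since "promoter" has no universal definition. Ties
among genes offering the same feature break by smallest |distance to TSS|,
then lexicographic gene id, so calls are invariant to gene-list order.
Distal peaks still carry a nearest-TSS gene so gene-level set analyses can
include distal regulatory regions. UTRs are folded into `exon` (the gene
table carries no UTR structure) and introns are not split by rank.

## DEG sets and overlap statistics

A gene is differentially expressed when |log2FC| ≥ log2(1.5) ≈ 0.585 and
BH-adjusted p ≤ 0.05; genes with missing adjusted p stay in the universe
but in neither set. The universe is the set of tested genes in the table —
not all annotated genes — which is the conservative GeneOverlap-style
choice. Overlap significance is the one-sided enrichment tail
P(X ≥ |A∩B|), X ~ Hypergeom(N, |A|, |B|); the odds ratio comes from the
2×2 table with a 0.5 continuity correction only when a cell is zero.
Cluster-wise DEG enrichment runs this test per cluster × direction and
BH-corrects within that family (each analysis panel is its own test
family rather than pooling all tests globally); the per-cluster median
log2FC is annotated over member DEGs, flagged when a cluster has none.

## Mechanism models

Both classifiers are staged set intersections with per-gene provenance
flags. Repression: candidate = decreased-in-KD ∩ H3K27ac-loss genes;
confirmed = candidate ∩ (increased-under-HDAC-inhibitor \ inhibitor
responders under control knockdown). The control-arm exclusion removes
TF-independent inhibitor effects and applies only to the repression arm —
the recruitment arm instead requires *non*-response. Recruitment:
candidate = increased-in-KD ∩ H3K27ac-gain; bound = candidate ∩ TF-bound
genes; confirmed = bound genes absent from both inhibitor DEG directions
at the same thresholds as the main DEG rule ("does not alter
transcription" needs an operational cutoff; reusing the DEG rule is the
declared choice). Differential-acetylation regions map to genes through
the annotation module's assigned gene (gene-level matching; region-level
matching would need region identities the inputs do not carry).

## Motifs

PWMs are probability matrices over {A,C,G,T} with uniform 0.25 background
by default; JASPAR-style count matrices are converted with a +0.8 total
pseudocount split by background. Scanning scores log2(p/background) in
bits on both strands; a position is a hit when it reaches 0.8 × the PWM's
maximum achievable score, windows with N at any informative position score
−∞, and overlapping same-strand hits collapse to the best-scoring
position. Positional preference compares the fraction of hits within
±20 bp of the summit to the uniform expectation (41/201 for a ±100 bp
scan) with binomial tails; fewer than 20 hits yields a flagged `uniform`
call. Cluster-wise enrichment counts presence/absence per peak and forms
z = (obs − n·p̂)/√(n·p̂(1−p̂)) against the pooled per-peak rate p̂ across
clusters (a reconstruction of heatmap-style motif z-scores; degenerate
p̂ ∈ {0,1} is flagged rather than scored). Size-weighted z-scores sum to
zero by construction.

## Binding modes

Peaks of two TFs chain into connected components via partner overlaps
(≥1 bp default); each component becomes one merged shared region, and
unlinked peaks stay unique. Differential binding per region uses
log2FC = log2((c_kd+0.5)/s_kd) − log2((c_ctrl+0.5)/s_ctrl) and an exact
two-sided conditional binomial test of c_kd given the total with success
probability s_kd/(s_kd+s_ctrl) — a deliberate replicate-free replacement
for negative-binomial differential-binding machinery, appropriate for
n = 1–2 ChIP designs; `gain`/`loss` requires BH-p ≤ 0.05 and
|log2FC| ≥ 1. `unchanged` means failing either criterion, not evidence of
equivalence. Modes: cooperative = both reciprocal calls loss;
competitive = at least one gain with no loss; independent = both
unchanged; asymmetric = the rest (loss paired with gain or unchanged).
Motif presence refines cooperative regions into shared-site vs
adjacent-site binding.

## Synthetic data

All generators draw from named substreams of a single root seed
(`SeedSequence([seed, crc32(name)])`), so regenerating one component never
perturbs another and runs are platform-stable. Coverage is written at
10-bp bedGraph resolution as per-bp rates whose region integrals recover
the sampled Poisson counts.

What is emulated: per-bin Poisson background (rate 1.0 per 10-bp bin),
Gaussian peak bumps (sd 150 bp) with Gamma(shape 4, scale 5) amplitudes
(mean 20), knockdown factors 1.0 / 2.0 / 0.5 for stable / gain / loss
classes; DEG tables with null genes log2FC ~ N(0, 0.2), padj ~
U(0.05, 1) and planted genes |log2FC| ~ N(1.5, 0.3) (truncated above the
threshold), padj ~ U(0, 0.01); motif placements N(0, 5 bp) at the center
vs |offset| ~ U(40, 100 bp) in the flanks; TF-pair regions with planted
log2 effect 1.5 under the partner's knockdown. Mechanism-class genes are
consistent across every required input set by construction; optional
decoys satisfy the candidate criteria but respond to the inhibitor under
control knockdown, exercising the exclusion stage. Annotation noise
(null genes sprinkled into acetylation/bound/responder sets at 5–10%)
keeps the set algebra from being trivially separable.

What is not emulated: read-level sampling (no FASTQ, no mapping noise),
fragment-length and nucleosome structure, replicate dispersion,
correlated background, and realistic genome composition (sequence is
i.i.d. uniform). Recovery on this generator therefore demonstrates the
correctness and calibration of the analysis logic — not performance on
real libraries, where dispersion and mappability artifacts dominate.

## Problem sizes and numerics

The validation suite uses 600 peaks (200 per class) for clustering
recovery, 2,000 genes (30 repression / 10 recruitment / 1,960 null) for
mechanism recovery, 500 peaks × 100 replicates per motif geometry, and
300 regions × 10 seeds for binding modes — sizes at which every planted
effect is comfortably detectable while the full suite runs in minutes on
one core. Exactness checks (hypergeometric and binomial tails) compare
against integer-arithmetic enumeration to 1e-12. Matrix extraction is
validated against per-bp integration to 1e-9. The pipeline writes floats
with shortest round-trip representation so read→write→read is exact and
double runs are byte-identical; the manifest records config hash and
SHA-256 of every input and output and deliberately contains no
timestamps.

## Known limitations

- The conditional binomial test is anticonservative under overdispersion;
  with replicates, a negative-binomial framework would be preferable.
- Gene models are single-isoform; promoter/exon calls ignore alternative
  TSSs.
- Motif scanning uses a 0-order background; CpG or repeat structure in
  real genomes would shift the hit-score null.
- The positional-preference null assumes hits can occur uniformly across
  the scan window, which ignores sequence-composition gradients around
  real summits.
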