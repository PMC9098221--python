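# Methods

## Coordinates and signal model

All coordinates are 0-based half-open, the native convention of BED,
bedGraph and refGene `txStart`/`txEnd`; nothing is ever shifted. A
coverage track is a piecewise-constant density (signal per base) over
sorted, non-overlapping runs; uncovered bases have value 0, so the mean
intensity of any window is well defined. The intensity of a window is its
mean density — total overlapping signal mass divided by window length —
not the sum, so clamped windows of unequal length stay comparable. Run
boundaries inside a window contribute exact fractional overlap, which is
what lets a per-base brute-force oracle check the implementation to 1e-9.

Track normalization rescales all runs so the total mass (Σ value × length)
equals a target, 1e6 by default — the reads-per-million analog of
normalizing by total read count. It is exact, idempotent at the target
mass, and commutes with window intensity up to the scale factor.

## Promoter catalog

Protein-coding transcripts are those with the `NM_` accession prefix and
length strictly greater than 2,000 bp (a 2,000-bp transcript is dropped).
The TSS of a + strand transcript is `txStart`; of a − strand transcript,
`txEnd − 1` — the terminal base of the half-open span, i.e. the biological
5′ end. Transcripts sharing (chromosome, strand, TSS) merge into one
promoter. Both choices are configurable: the strand key matters for
divergent promoter pairs at coincident coordinates, and dedup without
strand is available via `CatalogParams(dedup_by_strand=False)`.

The quantification window is −500/+1000 bp around the TSS along
transcription: `[tss−500, tss+1000)` on +, and its reflection about the
TSS base, `[tss−999, tss+501)`, on −. All region placement (promoter
windows, TSS subregions, profile-matrix bins) mirrors the same way, so
strand-reflection symmetry is a package-wide invariant tested directly.

## Classification

Thresholds are linear-interpolation quantiles at rank h = 1 + (N−1)q
(`numpy.quantile`, method "linear"). Low promoters satisfy
H3K4me3 < Q1 strictly; bivalent promoters are non-Low with
H3K27me3 > Q3 strictly, Q3 computed over the whole catalog, not the
High subset. The strict-below count on N distinct values with (N−1)q
non-integer is ⌊h⌋ — for N = 23,927 and q = 0.25, h = 5,982.5 and the
Low count is exactly 5,982. Under ties the rule degrades gracefully:
identical values are never strictly below their own quantile. The
classification depends only on ranks within each intensity list, so it is
invariant under any strictly increasing per-list transform. Replicate
tracks for one mark are combined by averaging per-window intensities
after per-track normalization; averaging is symmetric and scale-stable,
and pooling instead is a caller-side substitution of the track list.

## TSS subregions and clusters

Defaults bracket canonical −1/+1 nucleosome positions: Upstream
[−300,−100), Center [−100,+100), Downstream [+100,+300) bp relative to
the TSS, transcription-oriented, configurable as any ordered disjoint
triplet. Fold-change calls use ε-stabilized ratios with ε = 0.25 and a
1.5-fold threshold, both boundaries inclusive on the changed side. The
cluster table is the five call pairs containing at least one DECREASED
and no double-INCREASE; any pair with a DECREASED flank is by
construction one of the five, so every selected "decreased TSS" receives
exactly one cluster. The H3K4me3-Low class is excluded from the decreased
set by the caller, as a separate explicit step, because Low promoters
carry almost no BRG1 signal and their ratios are pseudocount-dominated.

The symmetric pseudocount keeps log ratios finite and antisymmetric at
zero coverage, at the cost of a compression bias when intensities are
within an order of magnitude of ε; with the generator's default depths,
scored regions carry ≥ 50 expected fragments and the bias is well inside
the 1.5-fold margin.

## Peak operations

Merging takes the interval union per chromosome; bookended intervals
(end = start) coalesce, since half-open adjacency is contiguous coverage.
Nearby assignment emits one row per (anchor, query) pair within the edge
distance — anchors are deliberately duplicated across rows, matching
heatmap-row bookkeeping where a peak with two nearby partners appears
twice — and drops anchors with no partner. The optional unique-query mode
keeps each query's single closest anchor. Equal splits rank by descending
key with (chrom, start) tie-breaks and give High ⌊N/2⌋ elements, Low the
remainder: 34,771 → 17,385/17,386, 67,447 → 33,723/33,724.

Annotation enrichment is a deliberately simple binomial model: a peak
belongs to an annotation when its midpoint falls inside it; expected
counts are N × (annotation bp / genome bp); enrichment is
log2((obs+0.5)/(exp+0.5)); the p-value is the binomial upper tail (lower
tail under depletion). This is *not* comparable in magnitude to
annotation tools that use hierarchical assignment and curated
backgrounds; it is a coherent additive model for ranking and testing.
Enrichment rises monotonically with the assumed genome size at fixed
observed counts, since a larger background shrinks the expectation.

## DEG linkage and tests

DEG calls apply the printed rule with inclusive boundaries: UP when
p ≤ 0.05 and linear fold change ≥ 1.5; DOWN when p ≤ 0.05 and fold
change ≤ 1/1.5. The expression table's fold change is taken as a linear
ratio (KD over control). Each down-regulated DEG TSS links to its single
closest BRG1 peak within 2 kb and closest ATAC peak within 500 bp;
equidistant ties resolve toward the transcription-upstream peak, then by
genomic position, purely for determinism. Mean differential intensity is
the arithmetic mean over linked peaks of log2((kd+ε)/(control+ε)) on the
peak interval. Rank tests (unpaired rank-sum, paired signed-rank) use
exact null enumeration up to n = 10 per sample and the normal
approximation with continuity correction beyond; identical paired
samples are a degenerate-test error rather than p = 1.

## Synthetic-data generator

The generator emulates the signal structure the pipeline is built to
read out, with every random draw governed by one seed (substreams per
generator function, so the functions compose in any order).

* **Genes.** 400 transcripts by default on two 2-Mb chromosomes, TSSs on
  a ~10-kb grid (snapped to the 10-bp sampling bin) so neighboring
  promoter windows never interact; random strands; categorical fractions
  of NR_ accessions (10%), sub-2-kb transcripts (5%) and duplicate-TSS
  transcripts (10%) exercise each catalog filter.
* **Classes and marks.** Each surviving site draws a class with
  probabilities 0.25/0.51/0.24 (Low/Only/Bivalent, mirroring the
  published 5,982/12,305/5,640 proportions). Mark densities are plateaus
  over the −500/+1000 window: (H3K4me3, H3K27me3) = (1, 2) for Low,
  (10, 1) for Only, (8, 8) for Bivalent, in fragments per base at unit
  depth.
* **BRG1 and ATAC.** BRG1 is two Gaussian bumps (σ = 50 bp) at −200 and
  +150 bp, transcription-oriented — the −1/+1 nucleosome positions —
  with amplitude 8 (Only), 4 (Bivalent), 0.5 (Low): high, moderate, low.
  ATAC is a single NFR bump at the TSS (σ = 60 bp) with the same
  per-class amplitude pattern.
* **Knockdown.** Each non-Low site draws Cluster1–5 (12% each) or
  unaffected (40%); Low sites are always unaffected. The knockdown track
  multiplies the upstream/downstream bump amplitudes by 2^effect with
  per-cluster effects (−1.5,−1.5), (−1.5,0), (0,−1.5), (−1.5,+1.0),
  (+1.0,−1.5) log2; knockdown accessibility shifts by half the mean BRG1
  effect (coupling 0.5). Effect magnitudes sit comfortably above the
  1.5-fold (0.585 log2) calling threshold, which is what a ≥ 95%
  recovery claim is calibrated against.
* **Noise.** Fragment counts per 10-bp bin are Poisson with mean
  density × bin × depth; stored run values are counts per base, so
  doubling depth doubles expected track mass and the pipeline's
  normalization step is doing real work. Noise-free mode stores the
  expected density directly. Defaults give ≥ 50 expected fragments per
  scored region (≥ 1,500 per mark window).
* **Peaks and expression.** One BRG1 peak per bump and one ATAC peak per
  NFR at the true locations (±2σ), plus optional decoy BRG1 peaks in
  gene deserts that nearby-assignment must discard. The expression table
  down-regulates genes at clustered promoters with probability 0.7
  (fold change ~0.5, p < 0.01) and up-regulates a 5% sprinkling of the
  rest, so the DEG-linkage stage has signal to find.

**What the generator does not emulate** — and therefore what passing
recovery tests do not show about real data: mappability and GC bias,
fragment-length structure, replicate correlation, enhancer signal,
overlapping or closely spaced promoters, copy-number variation, and
peak-caller boundary error (peaks sit at their true locations). Recovery
accuracies here measure the pipeline's conventions and arithmetic, not
robustness to those artifacts.

## Evaluation choices

Cluster recovery is scored on non-Low promoters, mirroring the analysis
flow that excludes H3K4me3-Low before clustering. Effect recovery (mean
absolute error of per-region log2 fold changes, evaluated at 10× depth)
uses depth-matched raw tracks and no pseudocount: the two simulated
conditions have identical sequencing depth by construction, so the raw
ratio is the direct estimate. Under a genuine global occupancy loss,
total-count normalization rescales the knockdown track upward and
compresses every per-region fold change (~0.17 log2 at the default
cluster mix) — a real property of depth-normalized differential
analysis, not an implementation artifact; the 1.5-fold cluster calls
absorb it easily, which is why cluster assignment still runs on
normalized tracks.

## Problem sizes and determinism

Default runs use 400 genes (~300 promoters) at depth 1, with the
effect-recovery check at depth 10; the full test suite and the
acceptance script each complete in seconds. Pipeline runs are
byte-deterministic under a fixed seed: rerunning with the same
configuration reproduces `summary.json` exactly.
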