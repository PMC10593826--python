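# Methods

This note documents the models and procedures implemented in `myomics`,
the parameters that matter, the synthetic data the test suite runs on, and
the numerical choices made where the design was genuinely open.

## Study design emulated

A four-stage postnatal muscle time course (D3, M3, M6, M12) with three
RNA-seq replicates and two WGBS/ATAC replicates per stage.  The six
unordered stage pairs define the differential comparisons; the phenotype of
interest is the fiber cross-sectional area (CSA), which grows across
stages, and the slow-twitch fiber proportion, which falls.

## Fiber morphometry

Operator chain: Rec. 601 luminance → Gaussian smoothing (σ = 2 px) →
threshold (Otsu by default; fixed threshold available) with *interiors as
foreground* (WGA stains the boundary lattice bright) → opening (disk r = 2)
→ hole filling → 8-connected labeling → inclusive area filter
(1400–80 000 px) and circularity filter (0.2–1.0).

*Circularity* is the ISO shape factor 4πA/P².  The perimeter is the length
of the marching-squares boundary contour smoothed with a 7-point circular
moving average.  The raw digital chain overestimates smooth perimeters by
up to ~8 % (staircase bias), which would bias a circle's shape factor to
~0.91; the smoothed contour gives ≈1.00 for a disk of r = 80 px and ≈0.796
for a square (π/4 + 0.011).  Quantization can still push values slightly
above 1; they are clamped at comparison time.

*Adhesion splitting* is a distance-transform watershed with two guards:
(1) markers are h-maxima (h = 2 px) of the distance map, but every
connected component keeps at least its deepest point, so no fiber can be
dropped; (2) a watershed cut is kept only if the saddle between the two
regions is thinner than `neck_ratio` (default 0.75) times the smaller
region's inradius.  A true adhesion neck is much shallower than either
fiber's half-width, whereas an elongated single fiber has two deep maxima
joined by a wide saddle; an absolute depth criterion alone cannot separate
the two cases at any single h.  On 10 synthetic mosaics this yields fiber
counts of 48–50 out of 50 and a median mean-CSA error of 2.8 %, while two
overlapping disks are still split.

*Fiber typing* (ATPase mode): per-fiber mean interior intensity,
thresholded by Otsu over the per-fiber means; fibers below the threshold
(dark) are slow-twitch.  With fewer than two fibers or identical means the
classification is refused rather than guessed.

Group statistics are one-way ANOVA across stages and Welch's t for pairs
(scipy implementations); an all-zero-variance comparison is reported as a
flagged degenerate result (F = ∞, p = 0) rather than an exception.

The pixel size (µm/px) must always be supplied; no magnification default is
assumed.

## Expression stratification

Expression is treated as log2 CPM with a pseudocount of 1.  DEG selection
is strict on both criteria (`|log2FC| > 0`, `q < 0.05`), and the DEG
universe is the union over all six comparisons.  The differential test
shipped here (Welch's t per stage pair + Benjamini–Hochberg) is a stand-in
used for synthetic matrices; externally computed differential tables with
the same columns are accepted unchanged.

Spearman correlation uses midranked ties; p-values are exact permutation
enumerations for n ≤ 8 samples and the t-approximation otherwise.  Genes
with constant expression get ρ = NaN and are excluded downstream.

The SOM is one-dimensional in input (the ρ value) with an 8×1 grid,
100 epochs, learning rate 0.5 → 0.01 and Gaussian neighbourhood width
4 → 0.5, both decaying linearly; the codebook is initialized at evenly
spaced input quantiles, and BMU ties resolve to the lowest node index.
Codebook weights are convex updates of inputs, so they remain inside the
data range (a property the suite checks).  The two-group cut is
complete-linkage agglomerative clustering of the codebook at k = 2; the
group with higher mean ρ is labeled G1 by convention (the source analysis
does not define the mapping).

Fuzzy c-means uses the canonical updates (fuzzifier m = 2, tol 1e-6) on
per-gene z-scored stage means; a point coinciding with a centroid takes
membership 1 there (the d → 0 limit).  Cluster-to-tendency naming
correlates centroids with three canonical shapes — T1 (0, 2, 1, −1), T2
monotone, T3 = −T1 — and takes the optimal one-to-one assignment
(Hungarian).  T3 is the *vertical* mirror of T1: reversing a rise-then-fall
profile in time still rises before it falls, so mirroring must be a
negation for "fall-then-rise" to mean anything.

Applying c = 3 inside a group that contains a single planted shape splits
that shape across clusters (the fitted centroids are near-collinear); with
real, heterogeneous data each group carries all three tendencies.  The
pooled-profile fit is therefore what the recovery tests measure.

## Genomic regions

Internal coordinates are 0-based half-open everywhere; GTF (1-based closed)
and Bismark cov (1-based) are converted at file boundaries only.  The
promoter is the 3 kb strand-aware window upstream of the TSS; "downstream"
is the symmetric 3 kb window past the gene end.  A peak is annotated by its
midpoint against fine features in the precedence order promoter > 5'UTR >
3'UTR > exon > intron > downstream, collapsed to four categories
({promoter, 5'UTR} → upstream; {exon, intron} → gene body; {3'UTR,
downstream} → downstream; else distal).  The nearest gene is chosen by
absolute TSS distance with lexicographic tie-breaking.

The consensus filter stands in for IDR: a first-replicate peak survives if
it reciprocally overlaps (≥ 50 % of the shorter interval) a peak in every
other replicate, and the reported interval is the intersection of the
matched cluster.  Raising the overlap fraction can only shrink the output.
Externally computed IDR peaks in BED form can be used wherever consensus
output is consumed.

Differential accessibility is a transparent stand-in for a
negative-binomial model: counts are normalized by **median-of-ratios size
factors** (each sample divided by the median ratio of its counts to the
per-region geometric mean), log2(x+1)-transformed, tested by Welch's t and
BH-adjusted at FDR < 0.1.  Total-depth scaling is available as an option
but is *not* the default: when a fifth of regions genuinely lose
accessibility, depth scaling shifts every unchanged region and the caller
degenerates (in our conditions it called 197/200 regions and biased the
planted −2.0 effect to −1.77; with size factors it calls the 40 planted
regions at −1.97 and permuted labels produce ≈0 calls).  Known limitation:
with 4-vs-4 samples the small-sample t is anti-conservative, so the
realized FDR among calls (~25 % here) exceeds the nominal 10 %; the
planted-effect recall and the permutation null are unaffected.

## Methylome

A methylation track stores per-CpG methylated/unmethylated read counts and
the level m/(m+u); region-level methylation is the unweighted mean of CpG
levels (read-weighting available).  Cytosine context is CG / CHG / CHH by
strand-aware triplet inspection.  CpGs whose C or paired G position carries
a SNP are removed before segmentation.

Segmentation replaces a posterior-based reference segmenter with a
deterministic heuristic with the same class semantics: levels are smoothed
with a 5-CpG running mean; PMDs are runs of ≥ 101 CpGs whose smoothed level
stays in [0.3, 0.7] (runs closer than 1 kb merge); outside PMDs, maximal
runs of smoothed level < 0.5 become UMRs when ≥ 30 CpGs and LMRs otherwise;
the remainder is HMD.  The smoothing matters: windowed means straddling an
HMD/UMR boundary fall inside the PMD band and would otherwise plant
spurious PMDs at every sharp transition.  Segment boundaries fall midway
between adjacent CpGs of different classes, so the segments of a sample
tile the covered territory exactly — an invariant the suite asserts.
UMRs and LMRs are subsequently pooled under the LMR label; the two-sided
Wilcoxon rank-sum p comparing their per-segment means (exact for n ≤ 8) is
reported for the record, and the merge happens regardless of it.

The DMR caller stands in for a smoothed beta-binomial model: read counts
are pooled within each group, each common CpG gets a two-proportion z-test,
BH adjustment, and significant CpGs (q < 0.05, |Δ| ≥ 0.1) with the same
sign merge into regions across gaps ≤ 100 bp; regions need ≥ 3 CpGs.
Reported delta is group A − group B over member CpGs.  Flank profiles
compare the CpG-level mean inside each DMR with its ±500 bp flanks,
truncated at contig ends.

## Synthetic data

The generator's defaults are the study conditions of the test suite; every
planted object is recoverable by brute force from the files it writes.

* **Fiber mosaics** — Voronoi cells of 50 uniform seeds on a 900×900 px
  canvas (0.65 µm/px), boundaries dilated to ~3–4 px bright ridges
  (WGA-like), interiors dark, plus Gaussian pixel noise (σ = 4).  Truth
  areas are exact label-mask pixel counts.  ATPase mode gives slow fibers
  (30 % by default) darker interiors.
* **Expression** — piecewise-linear stage templates (T1 (0,2,1,−1); T2
  monotone −1.5→1.5; T3 = −T1; null flat) on a uniform 3–8 log2 CPM
  baseline, 20 % of genes per tendency, Gaussian noise σ = 0.1.  The DEG
  table carries the *exact* template log2FC with Welch q-values from the
  replicates.  The CSA phenotype rises (900 → 4800 µm², 5 % jitter); the
  slow-fiber proportion falls (0.45 → 0.10).  Note the planted ρ signs this
  implies: T2 = +1, T3 = +0.4, T1 = −0.4; only T2 genes are "strong"
  correlates that clear the |ρ| > 0.7 screen.
* **Methylome** — 25 000 CpGs uniform over 1 Mb; coverage 1 +
  Poisson(29) per CpG (a floor of one read avoids undefined levels);
  methylated counts Binomial(coverage, target) with targets from a
  repeating domain plan (HMD 0.85 / UMR 8 kb at 0.05 / LMR 600 bp at 0.20 /
  PMD 40 kb at 0.50).  The LMR block is 600 bp so that it cannot reach the
  30-CpG UMR threshold at this CpG density, keeping the planted classes
  consistent with their definitions.  Eight DMRs of 20 consecutive CpGs
  (internal gaps ≤ 80 bp — DMRs live in CpG-dense stretches) drop by 0.4 in
  the two late stages.
* **Peaks** — 200 core peaks of 400 bp on a regular grid, jittered ≤ 10 bp
  per replicate, plus 30 replicate-private noise peaks placed in
  per-replicate sub-slots so noise can never reproduce across replicates.
  Counts are Poisson around per-peak baselines (~500); 40 planted DARs are
  scaled by 2^−2 in the late stages (accessibility predominantly falls with
  age).
* **TSS interaction landscape** — 120 genes on a dedicated contig, windows
  never overlapping; 30 % each get a TSS peak, methylated window CpGs, or
  both.  Expression is baseline 5 plus 1.5 for a peak and minus 1.5 for
  methylation, so the planted class medians order idr_only > both >
  meth_only.
* **TF resources** — 60 uniform 200 bp sequences; three TFs with
  near-deterministic 10 bp PWMs (consensus probability 0.94) planted as
  exact consensus matches at recorded offsets/strands (sites never
  overlap); an edge table of 18 planted TF–target pairs plus 50 % decoys
  with unvalidatable TFs.

What the generator does **not** emulate: read-level data, mapper or
peak-caller artifacts, realistic genome composition, overdispersion beyond
Poisson/binomial, batch effects, or biological coupling between the omic
layers beyond the planted structures.  Passing tests therefore demonstrate
that the operators recover what they are defined to recover, not that the
stand-ins match the reference tools on real sheep data.

## TF networks

PWM log-odds scores are log2((p + ε·bg)/(1 + ε)/bg) in bits (pseudocount
ε = 0.01); scanning covers both strands, reports minus-strand hits at the
plus-strand coordinate of the leftmost base, scores ambiguous bases as
background (0 contribution), and defaults the threshold to 80 % of the
maximal attainable score.  TF validation requires stage-mean expression
≥ 1 log2 CPM (optionally membership in the DEG universe); names resolve
case-insensitively through an optional alias map.  Network edges are
exactly the edge-table rows whose TF is validated and whose target is a
candidate — the assembly can never invent an edge.  The fiber-type
subnetwork restricts targets to the intersection of a metabolic gene list
and the slow-fiber correlates.

## Integration

DAR–DEG pairs are matched on (nearest gene, comparison) and kept when the
fold-change signs agree and are nonzero; a gene with several DARs yields
several pairs.  The TSS±3 kb window is symmetric regardless of strand; a
"methylated site" is a CpG with coverage ≥ 5 and level ≥ 0.5 (both
configurable) — without the coverage floor, single stray reads would count
as methylation evidence, and without the level floor every unmethylated
CpG-island position would.  Over-representation is the upper-tail
hypergeometric P(X ≥ k) with BH across terms.  The class-expression
ordering (idr_only ≥ both ≥ meth_only medians) is *reported*, never
enforced: it holds on planted-effect data by construction and is an
empirical observation elsewhere.

## Problem sizes and determinism

The shipped defaults (50 fibers, 1000 genes, 25 000 CpGs, 200 peaks,
120 landscape genes) keep a full pipeline run at a few seconds and the
whole test suite under a minute, while leaving every recovery margin wide
(e.g. segmentation Jaccards ≥ 0.87 against a 0.8 bar across seeds).  All
randomness flows from a single integer seed through independent named
substreams (CRC-32 of the stream name spawns the generator), so every
output — images, cov files, BED files, tables — is byte-identical across
runs with the same configuration.

## Known limitations

* All differential statistics are transparent stand-ins (Welch t,
  two-proportion z) chosen for testability; they are less powerful and less
  calibrated than the dispersion-modeling tools they replace, and the DAR
  caller in particular over-calls at small n (see above).
* The consensus filter has no notion of signal-rank consistency, only of
  reciprocal overlap.
* Fiber morphometry assumes WGA-like polarity (dark interiors); reversed
  stains need a fixed threshold or inverted input.
* The exact Spearman permutation p is enumerated only for n ≤ 8
  (8! = 40 320 permutations); beyond that the t-approximation is used.
* `segment_methylome` classifies one sample at a time; replicate-aware
  segmentation is out of scope.
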