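# myomics

Multi-omics analysis of postnatal skeletal-muscle growth, built as a
reusable Python library with a thin command-line layer.  It reimplements a
desk-scale version of a four-stage (day 3, month 3, month 6, month 12)
muscle time-course analysis:

* **Fiber morphometry** — segment WGA-stained section images (bright
  extracellular lattice, dark fiber interiors), filter candidates by area
  (1400–80 000 px, inclusive) and circularity `4πA/P² ∈ [0.2, 1.0]`, and
  report the cross-sectional area (CSA, µm²) and — for ATPase-stained
  sections — the slow-twitch fiber proportion.
* **Expression stratification** — select DEGs per stage pair
  (`|log2FC| > 0`, `q < 0.05`, both strict), correlate each with the CSA
  phenotype by Spearman's ρ, cluster the 1-D ρ axis with a self-organizing
  map, cut the codebook into two groups (G1 = higher ρ) by complete-linkage
  hierarchical clustering, and soft-cluster z-scored stage profiles with
  fuzzy c-means (m = 2) into three tendencies: T1 rise-then-fall, T2
  monotone rise, T3 the mirror of T1.
* **Genomic regions** — gene models with the TSS−3 kb promoter convention,
  four-way peak annotation (upstream / gene body / downstream / distal by
  midpoint precedence), a reciprocal-overlap consensus filter standing in
  for IDR, and differential accessibility (median-of-ratios normalization,
  Welch's t on log2 counts, BH, FDR < 0.1).
* **Methylome** — Bismark-style coverage tracks, CG/CHG/CHH context calls,
  SNP-aware CpG filtering, segmentation into UMR / LMR / PMD / HMD domains,
  the LMR∪UMR merge with its Wilcoxon rank-sum check, a DMR caller
  (pooled two-proportion z per CpG, BH, same-sign merge) with ±500 bp flank
  profiles, and chromosome-level stage comparisons.
* **Integration** — DAR–DEG fold-change sign consistency, DMR-regulated
  genes, TSS±3 kb interaction classes (open chromatin only / methylation
  only / both) with expression contrasts, the slow-fiber correlate screen
  (`|ρ| > 0.7`, `p < 0.05`), and generic hypergeometric over-representation
  on GMT gene sets.
* **TF networks** — MEME-minimal PWM IO, log-odds motif scanning on both
  strands, expression-based TF validation, and TF→target network assembly
  against an hTFtarget-like edge table, plus the fiber-type metabolic
  subnetwork.

Every input can be produced by the built-in synthetic generator
(`myomics.synthetic`) with its ground truth recorded, so the full pipeline
runs and is tested without any sequencing data.

## Worked example

```python
from myomics import morphometry as mm, synthetic

cfg = synthetic.SimConfig(seed=7)              # 50 fibers, 0.65 um/px
rgb, _, truth = synthetic.make_fiber_image(cfg)
params = mm.MorphometryParams(pixel_size_um=cfg.pixel_size_um)
_, records, summary = mm.run_morphometry(rgb, params)
print(summary.n_fibers, round(summary.mean_csa_um2))
```

prints `50 6255` against a planted truth of 50 fibers with mean CSA
6499 µm² — a 3.8 % error from boundary-pixel ambiguity.  Two arithmetic
conventions used throughout: an intersection of 3066 genes over a union of
5535 is reported as a `55.4` % overlap share, and a log2 fold change of 2.5
prints as a `5.7`-fold linear change.

The `examples/` directory has one short script per capability
(`python examples/03_methylome_segmentation.py` segments a planted
methylome and calls its DMRs, printing the recovered domain classes and the
planted-vs-called deltas).

The same stages are scriptable from a shell:

```bash
myomics simulate --seed 2 --outdir sim/
myomics methdomains --cov sim/meth_D3_1.cov --out segments.bed
myomics run-all --seed 5 --outdir results/
```

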