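"""Synthetic multi-omics data with recorded ground truth.

Every input the pipeline consumes can be generated here with its planted
truth recorded, so downstream stages are testable without any sequencing
data: WGA-like fiber mosaics with exact per-fiber areas, stage-structured
expression matrices with planted temporal tendencies tied to a growing CSA
phenotype, methylomes with planted UMR/LMR/PMD/HMD domains and DMRs,
replicate ATAC peak sets with a reproducible core and planted accessibility
shifts, and peak sequences with planted motif occurrences plus a TF-target
edge table.

Distributional choices (Gaussian expression noise, binomial methylation
counts over Poisson coverage, Poisson peak counts) are artifact choices:
they make planted effects exactly recoverable, they are not claims about
any particular study's noise.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from skimage import morphology, segmentation

from .regions import GenomicInterval, bh_adjust
from .stratify import STAGES, TENDENCY_TEMPLATES
from . import methylome as meth

DEFAULT_SEGMENT_PLAN = (
    # repeating HMD background with embedded UMR / LMR / PMD blocks
    ("HMD", 60_000, 0.85), ("UMR", 8_000, 0.05),
    ("HMD", 60_000, 0.85), ("LMR", 600, 0.20),
    ("HMD", 60_000, 0.85), ("PMD", 40_000, 0.50),
)


@dataclass
class SimConfig:
    """Study conditions for every synthetic input.

    Defaults describe a desk-scale version of a four-stage postnatal
    time course (D3, M3, M6, M12) with three RNA replicates and two
    WGBS/ATAC replicates per stage.
    """

    seed: int = 0
    # fiber mosaic
    canvas_px: tuple = (900, 900)
    n_fibers: int = 50
    pixel_size_um: float = 0.65
    ridge_px: int = 3
    image_noise_sd: float = 4.0
    slow_fraction: float = 0.3
    # expression
    n_genes: int = 1000
    n_stages: int = 4
    reps_per_stage: int = 3
    tendency_fractions: tuple = (0.2, 0.2, 0.2)   # T1, T2, T3; rest null
    noise_sd: float = 0.1
    base_expr_range: tuple = (3.0, 8.0)
    csa_stage_means: tuple = (900.0, 2600.0, 3900.0, 4800.0)  # µm²
    csa_jitter_frac: float = 0.05
    # methylome
    chrom: str = "chr1"
    chrom_length_bp: int = 1_000_000
    n_cpgs: int = 25_000
    segment_plan: tuple = DEFAULT_SEGMENT_PLAN
    coverage_mean: float = 30.0
    meth_reps_per_stage: int = 2
    n_dmrs: int = 8
    dmr_delta: float = 0.4
    dmr_n_cpgs: int = 20
    dmr_max_gap_bp: int = 80
    # peaks
    n_core_peaks: int = 200
    peak_width_bp: int = 400
    peak_jitter_bp: int = 10
    n_noise_peaks: int = 30
    atac_reps_per_stage: int = 2
    peak_count_mean: float = 500.0
    n_dars: int = 40
    dar_effect_log2: float = 2.0
    # TF resources
    n_sequences: int = 60
    seq_length_bp: int = 200
    n_tfs: int = 3
    sites_per_tf: int = 10
    decoy_edge_fraction: float = 0.5

    def __post_init__(self):
        if self.n_fibers < 1 or self.n_genes < 1 or self.n_cpgs < 1:
            raise ValueError("counts must be positive")
        if sum(self.tendency_fractions) > 1 + 1e-9:
            raise ValueError("tendency fractions must sum to <= 1")
        for _, _, tm in self.segment_plan:
            if not (0 <= tm <= 1):
                raise ValueError("segment target methylation must lie in [0, 1]")
        h, w = self.canvas_px
        if h * w / self.n_fibers < 1400:
            raise ValueError(
                f"canvas {h}x{w} too small for {self.n_fibers} fibers of "
                ">=1400 px mean area")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per data type."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(zlib.crc32(stream.encode()),)))


# ---------------------------------------------------------------------------
# fiber mosaic
# ---------------------------------------------------------------------------

def make_fiber_image(cfg: SimConfig, mode: str = "wga"
                     ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Voronoi-like fiber mosaic with bright boundary ridges.

    Fibers are Voronoi cells of uniformly random seed points; cell
    boundaries are dilated to ~``ridge_px`` wide bright ridges (the WGA-like
    lattice) and interiors are dark, plus Gaussian pixel noise.  In ATPase
    mode interiors carry two intensity classes with ``slow_fraction`` of
    fibers dark (slow-twitch).  Returns (rgb uint8 image, label mask with 0
    on ridges, truth table with exact pixel areas).
    """
    rng = cfg.rng("fibers")
    h, w = cfg.canvas_px
    pts = rng.uniform([0, 0], [h, w], size=(cfg.n_fibers, 2))
    rows, cols = np.mgrid[0:h, 0:w]
    grid = np.column_stack([rows.ravel(), cols.ravel()])
    _, nearest = cKDTree(pts).query(grid)
    voronoi = (nearest + 1).reshape(h, w).astype(np.int32)

    boundary = segmentation.find_boundaries(voronoi, mode="thick")
    if cfg.ridge_px > 1:
        boundary = morphology.dilation(
            boundary, morphology.disk(max(1, cfg.ridge_px // 2)))
    labels = np.where(boundary, 0, voronoi)

    types = np.array(["fast"] * cfg.n_fibers, dtype=object)
    n_slow = int(round(cfg.slow_fraction * cfg.n_fibers))
    slow_idx = rng.choice(cfg.n_fibers, size=n_slow, replace=False)
    types[slow_idx] = "slow"

    interior = np.full((h, w), 60.0)
    if mode == "atpase":
        slow_labels = np.flatnonzero(types == "slow") + 1
        interior = np.where(np.isin(labels, slow_labels), 40.0, 110.0)
        interior = np.where(labels == 0, 110.0, interior)
    img = np.where(boundary, 220.0, interior)
    if cfg.image_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.image_noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    rgb = np.stack([img] * 3, axis=-1)

    rows_out = []
    for lab in range(1, cfg.n_fibers + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area == 0:
            continue
        r, c = np.nonzero(mask)
        rows_out.append({"label": lab, "area_px": area,
                         "centroid_row": float(r.mean()),
                         "centroid_col": float(c.mean()),
                         "type": types[lab - 1]})
    truth = pd.DataFrame(rows_out)
    return rgb, labels, truth


# ---------------------------------------------------------------------------
# expression time course
# ---------------------------------------------------------------------------

def make_expression(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame,
                                             pd.Series, pd.DataFrame]:
    """Stage-structured expression with planted temporal tendencies.

    Per-gene stage templates are piecewise-linear over the four stage points:
    T1 rises then falls, T2 rises monotonically, T3 is the mirror image
    (negation) of T1; null genes are flat.  Samples are template +
    N(0, noise_sd) on the log2 CPM scale.  The CSA phenotype increases
    across stages with within-stage jitter; the truth labels record each
    template's rank-correlation sign with it (T1 -, T2 +, T3 +) and flag
    the monotone T2 genes as the strong correlates.

    Returns (expression matrix, DEG table with *exact template* log2FC and
    Welch-test q-values, per-sample CSA phenotype, gene truth labels).
    """
    rng = cfg.rng("expression")
    stages = STAGES[: cfg.n_stages]
    genes = [f"gene{idx:05d}" for idx in range(cfg.n_genes)]
    n1, n2, n3 = (int(round(f * cfg.n_genes)) for f in cfg.tendency_fractions)
    tendency = np.array(["null"] * cfg.n_genes, dtype=object)
    tendency[:n1] = "T1"
    tendency[n1:n1 + n2] = "T2"
    tendency[n1 + n2:n1 + n2 + n3] = "T3"
    rng.shuffle(tendency)

    base = rng.uniform(*cfg.base_expr_range, size=cfg.n_genes)
    templates = np.zeros((cfg.n_genes, len(stages)))
    for t, shape in TENDENCY_TEMPLATES.items():
        templates[tendency == t] = shape[: len(stages)]
    templates = templates + base[:, None]

    samples = [f"{s}_{r + 1}" for s in stages for r in range(cfg.reps_per_stage)]
    stage_of_sample = np.repeat(np.arange(len(stages)), cfg.reps_per_stage)
    values = templates[:, stage_of_sample] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, len(samples)))
    expr = pd.DataFrame(values, index=genes, columns=samples)

    csa = pd.Series(
        np.asarray(cfg.csa_stage_means)[stage_of_sample]
        * (1.0 + rng.normal(0.0, cfg.csa_jitter_frac, size=len(samples))),
        index=samples, name="csa_um2")

    deg_frames = []
    for ai, bi in itertools.combinations(range(len(stages)), 2):
        xa = values[:, stage_of_sample == ai]
        xb = values[:, stage_of_sample == bi]
        with np.errstate(invalid="ignore"):
            _, p = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        deg_frames.append(pd.DataFrame({
            "gene": genes, "comparison": f"{stages[ai]}-{stages[bi]}",
            "log2fc": templates[:, bi] - templates[:, ai],  # exact planted effect
            "pvalue": p, "qvalue": bh_adjust(p),
        }))
    deg_table = pd.concat(deg_frames, ignore_index=True)

    # sign of the noiseless template's rank correlation with stage order:
    # T2 is monotone up (+1); T3 ends above where it starts (+0.4); T1 is the
    # mirror (-0.4); null genes are flat (0).  T2 genes are additionally the
    # strong correlates (|rho| = 1 at zero noise).
    template_rho = {
        t: stats.spearmanr(shape[: len(stages)], np.arange(len(stages)))[0]
        for t, shape in TENDENCY_TEMPLATES.items()}
    rho_sign = np.array([int(np.sign(template_rho.get(t, 0.0))) for t in tendency])
    labels = pd.DataFrame({"gene": genes, "tendency": tendency,
                           "rho_sign": rho_sign,
                           "strong_correlate": tendency == "T2"}).set_index("gene")
    return expr, deg_table, csa, labels


def make_slow_fraction_phenotype(cfg: SimConfig) -> pd.Series:
    """Per-sample slow-twitch fiber proportion, decreasing across stages.

    The proportion drops sharply after the earliest stage, mirroring the
    postnatal fast-fiber shift, so genes falling over time correlate
    positively with it.
    """
    rng = cfg.rng("slow_fraction")
    stages = STAGES[: cfg.n_stages]
    stage_means = np.linspace(0.45, 0.10, len(stages))
    samples = [f"{s}_{r + 1}" for s in stages for r in range(cfg.reps_per_stage)]
    stage_of_sample = np.repeat(np.arange(len(stages)), cfg.reps_per_stage)
    vals = stage_means[stage_of_sample] + rng.normal(0, 0.01, size=len(samples))
    return pd.Series(np.clip(vals, 0, 1), index=samples, name="slow_fraction")


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def plan_segments(cfg: SimConfig) -> list[tuple[str, int, int, float]]:
    """Tile the chromosome with the repeating segment plan.

    Returns (class, start, end, target_meth) with 0-based half-open
    coordinates; raises if the plan blocks would overlap (they are laid out
    sequentially so this only trips on non-positive lengths).
    """
    out = []
    pos = 0
    plan_cycle = itertools.cycle(cfg.segment_plan)
    while pos < cfg.chrom_length_bp:
        klass, length, tm = next(plan_cycle)
        if length <= 0:
            raise ValueError("segment plan lengths must be positive")
        end = min(pos + length, cfg.chrom_length_bp)
        out.append((klass, pos, end, tm))
        pos = end
    return out


def make_methylome(cfg: SimConfig) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Methylation tracks per sample with planted domains and DMRs.

    CpG positions are uniform over the chromosome; each CpG's coverage is
    1 + Poisson(coverage_mean - 1) (so no CpG is uncovered) and its
    methylated count is Binomial(coverage, target) where target comes from
    the planted segment class.  DMRs are planted inside HMD territory on
    runs of ``dmr_n_cpgs`` consecutive CpGs with internal gaps <=
    ``dmr_max_gap_bp`` (DMRs live in CpG-dense stretches); in the *late*
    stage group the target drops by ``dmr_delta``.

    Returns (tracks keyed "STAGE_rep", planted segment table, planted DMR
    table).  Group A = first two stages, group B = last two.
    """
    rng = cfg.rng("methylome")
    stages = STAGES[: cfg.n_stages]
    positions = np.sort(rng.choice(
        np.arange(1, cfg.chrom_length_bp), size=cfg.n_cpgs, replace=False))
    segments = plan_segments(cfg)
    seg_table = pd.DataFrame(segments, columns=["klass", "start", "end", "target"])

    target = np.empty(cfg.n_cpgs)
    bounds = seg_table["end"].to_numpy()
    seg_idx = np.searchsorted(bounds, positions - 1, side="right")
    target[:] = seg_table["target"].to_numpy()[seg_idx]
    klass_of_cpg = seg_table["klass"].to_numpy()[seg_idx]

    dmr_rows = []
    dmr_mask = np.zeros(cfg.n_cpgs, dtype=bool)
    in_hmd = klass_of_cpg == "HMD"
    gaps = np.diff(positions)
    candidates = []
    i = 0
    while i < cfg.n_cpgs - cfg.dmr_n_cpgs:
        j = i + cfg.dmr_n_cpgs - 1
        window_ok = (in_hmd[i:j + 1].all()
                     and (gaps[i:j] <= cfg.dmr_max_gap_bp).all())
        if window_ok:
            candidates.append((i, j))
            i = j + 50  # keep planted DMRs well separated
        else:
            i += 1
    chosen = candidates[:cfg.n_dmrs]
    if len(chosen) < cfg.n_dmrs:
        raise ValueError("chromosome too sparse to plant the requested DMRs")
    for i, j in chosen:
        dmr_mask[i:j + 1] = True
        dmr_rows.append({"chrom": cfg.chrom,
                         "start": int(positions[i] - 1), "end": int(positions[j]),
                         "first_cpg": i, "last_cpg": j,
                         "n_cpg": int(j - i + 1),
                         "target_a": float(target[i]),
                         "target_b": float(target[i] - cfg.dmr_delta)})
    dmr_table = pd.DataFrame(dmr_rows)

    late = set(stages[len(stages) // 2:])
    tracks = {}
    for s in stages:
        for r in range(cfg.meth_reps_per_stage):
            tgt = target.copy()
            if s in late:
                tgt[dmr_mask] = np.clip(tgt[dmr_mask] - cfg.dmr_delta, 0, 1)
            cov = 1 + rng.poisson(max(0.0, cfg.coverage_mean - 1), size=cfg.n_cpgs)
            m = rng.binomial(cov, tgt)
            tracks[f"{s}_{r + 1}"] = meth.make_track(cfg.chrom, positions, m, cov - m)
    return tracks, seg_table, dmr_table


# ---------------------------------------------------------------------------
# ATAC peaks
# ---------------------------------------------------------------------------

def make_peaks(cfg: SimConfig) -> tuple[dict, pd.DataFrame, list, pd.DataFrame]:
    """Replicate peak sets per stage plus a per-peak count matrix.

    A reproducible core of ``n_core_peaks`` is present in every replicate
    with boundary jitter <= ``peak_jitter_bp``; each replicate additionally
    carries private noise peaks.  Counts over core peaks are Poisson around
    a per-peak baseline; for the ``n_dars`` planted differential regions the
    rate in later stages is scaled by 2**(-dar_effect_log2) (accessibility
    predominantly *decreases* with age).

    Returns (replicate peak sets keyed "STAGE_rep", count matrix core x
    samples, reproducible core ids, planted DAR truth table).
    """
    rng = cfg.rng("peaks")
    stages = STAGES[: cfg.n_stages]
    spacing = cfg.chrom_length_bp // (cfg.n_core_peaks + 1)
    if spacing <= cfg.peak_width_bp + 2 * cfg.peak_jitter_bp:
        raise ValueError("chromosome too short for the requested core peaks")
    starts = np.arange(1, cfg.n_core_peaks + 1) * spacing
    core_ids = [f"peak{idx:04d}" for idx in range(cfg.n_core_peaks)]
    core = [GenomicInterval(cfg.chrom, int(s), int(s + cfg.peak_width_bp), ".",
                            pid) for s, pid in zip(starts, core_ids)]

    rep_sets = {}
    for s in stages:
        for r in range(cfg.atac_reps_per_stage):
            peaks = []
            for iv in core:
                j1 = int(rng.integers(-cfg.peak_jitter_bp, cfg.peak_jitter_bp + 1)) \
                    if cfg.peak_jitter_bp else 0
                j2 = int(rng.integers(-cfg.peak_jitter_bp, cfg.peak_jitter_bp + 1)) \
                    if cfg.peak_jitter_bp else 0
                peaks.append(GenomicInterval(iv.chrom, iv.start + j1,
                                             max(iv.start + j1 + 50, iv.end + j2),
                                             ".", iv.name))
            noise_w = cfg.peak_width_bp // 2
            # private noise peaks sit between core peaks, in a per-replicate
            # sub-slot so noise from different replicates can never overlap
            slot0 = cfg.peak_width_bp + 2 * cfg.peak_jitter_bp + 10
            slots = rng.choice(cfg.n_core_peaks, size=min(cfg.n_noise_peaks,
                                                          cfg.n_core_peaks),
                               replace=False)
            for k, slot in enumerate(slots):
                pos = int(slot) * spacing + slot0 + r * (noise_w + 10)
                if pos + noise_w >= cfg.chrom_length_bp:
                    continue
                peaks.append(GenomicInterval(cfg.chrom, pos, pos + noise_w,
                                             ".", f"noise_{s}_{r}_{k}"))
            rep_sets[f"{s}_{r + 1}"] = sorted(peaks, key=lambda p: p.start)

    dar_idx = rng.choice(cfg.n_core_peaks, size=cfg.n_dars, replace=False)
    dar_mask = np.zeros(cfg.n_core_peaks, dtype=bool)
    dar_mask[dar_idx] = True
    base_rate = rng.uniform(0.5, 1.5, size=cfg.n_core_peaks) * cfg.peak_count_mean
    late = set(stages[len(stages) // 2:])
    counts = {}
    for s in stages:
        for r in range(cfg.atac_reps_per_stage):
            rate = base_rate.copy()
            if s in late:
                rate[dar_mask] = rate[dar_mask] * 2.0 ** (-cfg.dar_effect_log2)
            counts[f"{s}_{r + 1}"] = rng.poisson(rate)
    count_matrix = pd.DataFrame(counts, index=core_ids)

    dar_truth = pd.DataFrame({
        "peak_id": [core_ids[i] for i in sorted(dar_idx)],
        "effect_log2": -cfg.dar_effect_log2,
    })
    return rep_sets, count_matrix, core, dar_truth


# ---------------------------------------------------------------------------
# TSS interaction landscape
# ---------------------------------------------------------------------------

def make_interaction_layout(cfg: SimConfig, n_genes: int = 120,
                            fractions=(0.3, 0.3, 0.3), window_bp: int = 3000,
                            peak_boost: float = 1.5, meth_penalty: float = 1.5
                            ) -> dict:
    """Genes with planted TSS-window regulatory evidence and coupled expression.

    Genes sit on a dedicated contig, far enough apart that TSS windows never
    overlap.  ``fractions`` of them get, in order: an open-chromatin peak at
    the TSS (idr_only), methylated CpGs in the window (meth_only), or both;
    the rest get neither.  Expression is a common baseline plus
    ``peak_boost`` for a peak and minus ``meth_penalty`` for methylation, so
    the planted medians order idr_only > both > meth_only.

    Returns gene models, per-replicate peak sets, a methylation track, a
    per-gene expression series and the truth class per gene.
    """
    from .regions import GeneModel

    rng = cfg.rng("interaction")
    chrom = "chrTSS"
    spacing = 2 * window_bp + 4000
    n1 = int(round(fractions[0] * n_genes))
    n2 = int(round(fractions[1] * n_genes))
    n3 = int(round(fractions[2] * n_genes))
    klasses = np.array(["idr_only"] * n1 + ["meth_only"] * n2 + ["both"] * n3
                       + ["none"] * (n_genes - n1 - n2 - n3), dtype=object)
    rng.shuffle(klasses)

    genes, peak_positions = [], []
    cpg_pos, cpg_target = [], []
    expr = {}
    for k in range(n_genes):
        tss = (k + 1) * spacing
        gid = f"tssgene{k:04d}"
        genes.append(GeneModel(gid, chrom, tss, tss + 2000, "+"))
        klass = klasses[k]
        has_peak = klass in ("idr_only", "both")
        has_meth = klass in ("meth_only", "both")
        if has_peak:
            peak_positions.append((gid, tss - 150))
        # a small CpG cluster inside the window; methylated only where planted
        for j in range(6):
            cpg_pos.append(tss + 300 + 40 * j)
            cpg_target.append(0.9 if has_meth else 0.05)
        expr[gid] = (5.0 + (peak_boost if has_peak else 0.0)
                     - (meth_penalty if has_meth else 0.0)
                     + float(rng.normal(0, cfg.noise_sd)))

    reps = []
    for _ in range(2):
        peaks = [GenomicInterval(chrom, p - 200, p + 200, ".", f"tss_{g}")
                 for g, p in peak_positions]
        reps.append(peaks)

    cpg_pos = np.array(cpg_pos)
    cov = 1 + rng.poisson(max(0.0, cfg.coverage_mean - 1), size=cpg_pos.size)
    m = rng.binomial(cov, np.array(cpg_target))
    track = meth.make_track(chrom, cpg_pos + 1, m, cov - m)  # 1-based cov dialect

    truth = pd.Series(klasses, index=[g.gene_id for g in genes], name="klass")
    return {"genes": genes, "replicate_peaks": reps, "track": track,
            "expression": pd.Series(expr, name="expr"), "truth": truth}


# ---------------------------------------------------------------------------
# TF resources
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def make_tf_resources(cfg: SimConfig) -> dict:
    """Peak sequences with planted motif sites, PWMs, and a TF-target table.

    Each TF gets a near-deterministic PWM (consensus probability 0.94) whose
    exact consensus is planted at recorded offsets/strands in a subset of
    uniform-background sequences.  The TF-target TSV holds the planted
    regulatory edges plus decoy edges for TFs/targets outside the planted
    set.

    Returns dict with keys: sequences (id -> str), pwms (tf -> 4 x L
    probability matrix), sites (DataFrame seq_id/tf/offset/strand),
    edges (planted TSV-shaped DataFrame), planted_edges (list of tuples).
    """
    rng = cfg.rng("tf")
    seq_ids = [f"seq{idx:03d}" for idx in range(cfg.n_sequences)]
    seqs = {sid: "".join(rng.choice(_BASES, size=cfg.seq_length_bp))
            for sid in seq_ids}

    motif_len = 10
    if motif_len >= cfg.seq_length_bp:
        raise ValueError("motif length must be below sequence length")
    tf_names = [f"TF{k + 1}" for k in range(cfg.n_tfs)]
    pwms, sites = {}, []
    occupied: dict[str, list] = {sid: [] for sid in seq_ids}
    comp = str.maketrans("ACGT", "TGCA")
    for tf in tf_names:
        consensus = "".join(rng.choice(_BASES, size=motif_len))
        mat = np.full((4, motif_len), 0.02)
        for i, b in enumerate(consensus):
            mat["ACGT".index(b), i] = 0.94
        pwms[tf] = mat
        host_ids = rng.choice(seq_ids, size=cfg.sites_per_tf, replace=False)
        for sid in host_ids:
            offset = None
            for _ in range(100):  # avoid clobbering another TF's planted site
                cand = int(rng.integers(0, cfg.seq_length_bp - motif_len + 1))
                if all(cand + motif_len <= s or e <= cand
                       for s, e in occupied[sid]):
                    offset = cand
                    break
            if offset is None:
                continue
            occupied[sid].append((offset, offset + motif_len))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = consensus if strand == "+" else consensus.translate(comp)[::-1]
            s = seqs[sid]
            seqs[sid] = s[:offset] + planted + s[offset + motif_len:]
            sites.append({"seq_id": sid, "tf": tf, "offset": offset,
                          "strand": strand, "consensus": consensus})
    site_table = pd.DataFrame(sites)

    targets = [f"gene{idx:05d}" for idx in range(40)]
    planted_edges = []
    for tf in tf_names:
        for t in rng.choice(targets, size=6, replace=False):
            planted_edges.append((tf, str(t)))
    planted_edges = sorted(set(planted_edges))
    n_decoys = int(round(cfg.decoy_edge_fraction * len(planted_edges)
                         / max(1e-9, 1 - cfg.decoy_edge_fraction)))
    decoys = []
    for k in range(n_decoys):
        decoys.append((f"DECOYTF{k}", f"decoygene{k:03d}"))
    edges = pd.DataFrame(planted_edges + decoys, columns=["tf", "target"])
    edges["evidence"] = "synthetic"
    alias = {tf: f"gene{k:05d}" for k, tf in enumerate(tf_names)}
    return {"sequences": seqs, "pwms": pwms, "sites": site_table,
            "edges": edges, "planted_edges": planted_edges, "alias": alias}


# ---------------------------------------------------------------------------
# file export helpers
# ---------------------------------------------------------------------------

def write_fasta(path, sequences: dict) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_meme(path, pwms: dict, background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """MEME minimal-format PWM file."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.3f} C {:.3f} G {:.3f} T {:.3f}\n\n".format(*background))
        for tf, mat in pwms.items():
            fh.write(f"MOTIF {tf}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {mat.shape[1]} "
                     f"nsites= 20 E= 0\n")
            for col in mat.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def make_gene_models(cfg: SimConfig, n_genes: int = 50,
                     gene_length: int = 2000, spacing: int | None = None):
    """Evenly spaced synthetic gene models on the synthetic chromosome."""
    from .regions import GeneModel
    rng = cfg.rng("genes")
    spacing = spacing or max(gene_length + 6001, cfg.chrom_length_bp // (n_genes + 1))
    genes = []
    for k in range(n_genes):
        start = (k + 1) * spacing
        if start + gene_length >= cfg.chrom_length_bp:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{k:05d}", cfg.chrom, start,
                               start + gene_length, strand))
    return genes


def truth_to_json(path, **tables) -> None:
    """Dump truth tables (DataFrames / Series / scalars) to one JSON file."""
    payload = {}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            payload[name] = obj.to_dict(orient="list")
        elif isinstance(obj, pd.Series):
            payload[name] = obj.to_dict()
        else:
            payload[name] = obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
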