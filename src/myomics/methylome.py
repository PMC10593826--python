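"""Per-CpG methylation handling.

Bismark-style coverage tracks, cytosine context classification, SNP-aware
filtering, segmentation of a methylome into UMR / LMR / PMD / HMD domains,
the LMR+UMR merge with its rank-sum check, differential-methylation calling
with flank profiles, and chromosome-level stage comparisons.

A methylation *track* is a DataFrame with columns
``chrom, pos, meth, unmeth, level`` where ``pos`` is the 1-based position of
the cytosine (Bismark cov dialect) and ``level = meth / (meth + unmeth)``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GenomicInterval, bh_adjust

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["chrom", "pos", "meth", "unmeth", "level"]

SEGMENT_CLASSES = ("UMR", "LMR", "PMD", "HMD")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 0-based half-open, like every internal interval
    end: int
    klass: str
    n_cpg: int
    mean_meth: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.klass)


@dataclass(frozen=True)
class DMRRecord:
    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_meth_a: float
    mean_meth_b: float
    qvalue: float

    @property
    def delta(self) -> float:
        return self.mean_meth_a - self.mean_meth_b

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class SegmentationParams:
    """Windowed segmentation heuristic parameters.

    The reference posterior-based segmenter is replaced by a deterministic
    smoothing + run-length heuristic with the same class semantics; all
    parameters are exposed and precomputed segment BEDs are accepted wherever
    segments are consumed.
    """

    pmd_window_cpgs: int = 101     # minimum CpGs in a PMD
    pmd_band: tuple = (0.3, 0.7)   # smoothed-level band defining "partial"
    low_cutoff: float = 0.5        # smoothed level below this -> low region
    umr_min_cpgs: int = 30         # low regions with >= this many CpGs are UMRs
    merge_gap_bp: int = 1000       # PMD candidate runs closer than this merge
    smooth_cpgs: int = 5           # running-mean window (CpGs), odd


# ---------------------------------------------------------------------------
# coverage-file IO
# ---------------------------------------------------------------------------

def read_cov(path) -> pd.DataFrame:
    """Read a Bismark-style .cov file into a track.

    Columns on disk: chrom, start, end (both 1-based, equal for CpGs),
    methylation percentage in [0, 100], methylated count, unmethylated count.
    Lines with zero total reads are rejected; a >0.5 %-point mismatch between
    the stated percentage and the counts triggers an integrity warning.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "end", "pct", "meth", "unmeth"],
                     dtype={"chrom": str})
    total = df["meth"] + df["unmeth"]
    if (total < 1).any():
        bad = int((total < 1).sum())
        raise ValueError(f"{path}: {bad} CpG line(s) with zero total reads")
    level = df["meth"] / total
    mismatch = (df["pct"] - 100.0 * level).abs() > 0.5
    if mismatch.any():
        logger.warning("%s: %d line(s) where %%meth disagrees with counts by >0.5",
                       path, int(mismatch.sum()))
    out = df[["chrom", "pos", "meth", "unmeth"]].copy()
    out["level"] = level
    return out.reset_index(drop=True)


def write_cov(path, track: pd.DataFrame) -> None:
    df = track.copy()
    pct = 100.0 * df["meth"] / (df["meth"] + df["unmeth"])
    out = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"], "end": df["pos"],
        "pct": pct.map(lambda x: f"{x:g}"),
        "meth": df["meth"], "unmeth": df["unmeth"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def make_track(chrom, pos, meth, unmeth) -> pd.DataFrame:
    meth = np.asarray(meth)
    unmeth = np.asarray(unmeth)
    return pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos), "meth": meth, "unmeth": unmeth,
        "level": meth / (meth + unmeth),
    })


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(sequences, positions) -> list[str]:
    """Classify cytosine context (CG / CHG / CHH) at 1-based positions.

    ``sequences`` maps contig name to sequence (a dict, or any mapping such
    as a pyfaidx.Fasta); ``positions`` is an iterable of (chrom, pos, strand).
    For minus-strand cytosines the reverse complement is inspected.  H is any
    of A, C, T; bases past the contig end make the pattern fall through to
    CHH (a lone trailing C has no G to pair with).
    """
    comp = str.maketrans("ACGTacgt", "TGCATGCA")
    out = []
    for chrom, pos, strand in positions:
        seq = str(sequences[chrom]).upper()
        i = pos - 1
        if not (0 <= i < len(seq)):
            raise IndexError(f"position {chrom}:{pos} beyond contig of length {len(seq)}")
        if strand == "-":
            window = seq[max(0, i - 2): i + 1].translate(comp)[::-1]
        else:
            window = seq[i: i + 3]
        if window[0:1] != "C":
            raise ValueError(f"{chrom}:{pos}({strand}) is not a cytosine")
        if len(window) >= 2 and window[1] == "G":
            out.append("CG")
        elif len(window) >= 3 and window[2] == "G":
            out.append("CHG")
        else:
            out.append("CHH")
    return out


def context_fractions(contexts) -> dict[str, float]:
    """Fractions of methylation calls per cytosine context."""
    s = pd.Series(list(contexts))
    frac = s.value_counts(normalize=True)
    return {c: float(frac.get(c, 0.0)) for c in ("CG", "CHG", "CHH")}


# ---------------------------------------------------------------------------
# SNP-aware filtering
# ---------------------------------------------------------------------------

def read_vcf_positions(path) -> set[tuple[str, int]]:
    """(chrom, 1-based pos) of every record in a minimal VCF."""
    out = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            out.add((f[0], int(f[1])))
    return out


def filter_snp_cpgs(track: pd.DataFrame, snp_positions) -> pd.DataFrame:
    """Drop CpGs whose C position or the paired G position carries a SNP.

    ``pos`` is the C of a CpG dyad; the G sits at ``pos + 1``.
    """
    snps = set(snp_positions)
    if not snps:
        return track.copy()
    keep = [
        (c, p) not in snps and (c, p + 1) not in snps
        for c, p in zip(track["chrom"], track["pos"])
    ]
    return track.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _running_mean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or x.size == 0:
        return x.astype(float)
    pad = w // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(xp, kernel, mode="valid")


def segment_methylome(track: pd.DataFrame,
                      params: SegmentationParams | None = None) -> list[Segment]:
    """Partition a single-sample methylome into UMR/LMR/PMD/HMD segments.

    Partially methylated domains are found first and masked; the remaining
    territory is split into low-methylation runs (UMR if >= ``umr_min_cpgs``
    CpGs, else LMR) and highly methylated background (HMD).  Levels are
    smoothed with a short running mean over CpGs so single-read noise does
    not fragment runs; a PMD is a run of at least ``pmd_window_cpgs`` CpGs
    whose smoothed level stays inside ``pmd_band`` (qualifying runs closer
    than ``merge_gap_bp`` merge).  Segment boundaries fall halfway between
    adjacent CpGs of different classes, so the segments of a sample tile the
    covered territory exactly.
    """
    params = params or SegmentationParams()
    out: list[Segment] = []
    for chrom, sub in track.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        lev = sub["level"].to_numpy(dtype=float)
        n = len(pos)
        if n == 0:
            continue
        smooth = _running_mean(lev, params.smooth_cpgs)
        klass = np.full(n, "HMD", dtype=object)

        # 1) PMDs: long runs of "partial" smoothed level, merged across short gaps
        lo, hi = params.pmd_band
        in_band = (smooth >= lo) & (smooth <= hi)
        pmd_runs = _merge_runs(_runs(in_band), pos, params.merge_gap_bp)
        for s, e in pmd_runs:
            if e - s >= params.pmd_window_cpgs:
                klass[s:e] = "PMD"

        # 2) outside PMDs: low-methylation runs
        low = (smooth < params.low_cutoff) & (klass != "PMD")
        for s, e in _runs(low):
            klass[s:e] = "UMR" if e - s >= params.umr_min_cpgs else "LMR"

        # 3) convert per-CpG classes to tiling segments
        for s, e in _runs_of_labels(klass):
            start = int(pos[s] - 1) if s == 0 else int((pos[s - 1] + pos[s] - 1) // 2)
            end = int(pos[e - 1]) if e == n else int((pos[e - 1] + pos[e] - 1) // 2)
            out.append(Segment(chrom, start, end, str(klass[s]), e - s,
                               float(lev[s:e].mean())))
    return out


def _runs(mask: np.ndarray):
    """[start, end) index runs of True."""
    runs = []
    i, n = 0, mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _runs_of_labels(labels: np.ndarray):
    runs = []
    i, n = 0, labels.size
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def _merge_runs(runs, pos: np.ndarray, max_gap_bp: int):
    """Merge index runs whose genomic gap is <= max_gap_bp."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        prev = merged[-1]
        if pos[s] - pos[prev[1] - 1] <= max_gap_bp:
            prev[1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


def merge_lmr_umr(segments) -> tuple[list[Segment], float]:
    """Relabel UMR segments as LMR; report the rank-sum p first.

    The two low-methylation classes overlap strongly in per-segment mean
    level, so they are pooled; the two-sided Wilcoxon rank-sum p-value
    comparing per-segment means (exact for small samples) is returned for
    the record, and the merge is applied unconditionally.
    """
    lmr = [s.mean_meth for s in segments if s.klass == "LMR"]
    umr = [s.mean_meth for s in segments if s.klass == "UMR"]
    if lmr and umr:
        method = "exact" if max(len(lmr), len(umr)) <= 8 else "asymptotic"
        p = float(stats.mannwhitneyu(lmr, umr, alternative="two-sided",
                                     method=method).pvalue)
    else:
        p = float("nan")
        logger.warning("LMR/UMR merge: one class absent, rank-sum p undefined")
    merged = [
        Segment(s.chrom, s.start, s.end, "LMR" if s.klass == "UMR" else s.klass,
                s.n_cpg, s.mean_meth)
        for s in segments
    ]
    return merged, p


# ---------------------------------------------------------------------------
# differential methylation
# ---------------------------------------------------------------------------

def _pool_tracks(tracks) -> pd.DataFrame:
    pooled = None
    for t in tracks:
        g = t.groupby(["chrom", "pos"])[["meth", "unmeth"]].sum()
        pooled = g if pooled is None else pooled.add(g, fill_value=0)
    return pooled.astype(int)


def call_dmrs(tracks_a, tracks_b, min_delta: float = 0.1, min_cpgs: int = 3,
              max_gap_bp: int = 100, q_lt: float = 0.05) -> list[DMRRecord]:
    """Call differentially methylated regions between two sample groups.

    A transparent stand-in for a smoothed beta-binomial model: read counts
    are pooled within each group, each common CpG gets a two-proportion
    z-test, p-values are BH-adjusted, and significant CpGs
    (q < ``q_lt`` and |level difference| >= ``min_delta``) with the same
    difference sign merge into regions when separated by <= ``max_gap_bp``;
    regions with >= ``min_cpgs`` CpGs are reported.  Delta is reported as
    group A minus group B.
    """
    a = _pool_tracks(tracks_a)
    b = _pool_tracks(tracks_b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        logger.warning("call_dmrs: no common CpG positions between groups")
        return []
    a, b = a.loc[common], b.loc[common]
    na = (a["meth"] + a["unmeth"]).to_numpy(dtype=float)
    nb = (b["meth"] + b["unmeth"]).to_numpy(dtype=float)
    pa = a["meth"].to_numpy() / na
    pb = b["meth"].to_numpy() / nb
    pooled = (a["meth"].to_numpy() + b["meth"].to_numpy()) / (na + nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(pooled * (1 - pooled) * (1 / na + 1 / nb))
        z = np.where(se > 0, (pa - pb) / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(pvals)
    diff = pa - pb
    sig = (q < q_lt) & (np.abs(diff) >= min_delta)

    idx = common.to_frame(index=False)
    chroms = idx["chrom"].to_numpy()
    pos = idx["pos"].to_numpy()
    order = np.lexsort((pos, chroms))

    out: list[DMRRecord] = []
    members: list[int] = []

    def _flush():
        if len(members) >= min_cpgs:
            m = np.array(members)
            out.append(DMRRecord(
                chrom=str(chroms[m[0]]),
                start=int(pos[m[0]] - 1), end=int(pos[m[-1]]),
                n_cpg=len(m),
                mean_meth_a=float(pa[m].mean()), mean_meth_b=float(pb[m].mean()),
                qvalue=float(q[m].min()),
            ))
        members.clear()

    for i in order:
        if not sig[i]:
            continue
        if members:
            j = members[-1]
            same_chrom = chroms[i] == chroms[j]
            close = same_chrom and (pos[i] - pos[j] <= max_gap_bp)
            same_sign = np.sign(diff[i]) == np.sign(diff[j])
            if not (close and same_sign):
                _flush()
        members.append(i)
    _flush()
    return out


def dmr_flank_profile(dmrs, tracks: dict, flank_bp: int = 500) -> pd.DataFrame:
    """Mean methylation inside each DMR vs its +-``flank_bp`` flanks, per track.

    ``tracks`` maps a label (e.g. a stage) to a track.  Flank means use the
    CpGs available in the flanks (truncated at contig ends); a DMR with no
    flank CpGs in a track is flagged with NaN.
    """
    rows = []
    for label, track in tracks.items():
        for k, d in enumerate(dmrs):
            sub = track[track["chrom"] == d.chrom]
            p = sub["pos"].to_numpy()
            lev = sub["level"].to_numpy()
            inside = (p > d.start) & (p <= d.end)
            left = (p > d.start - flank_bp) & (p <= d.start)
            right = (p > d.end) & (p <= d.end + flank_bp)
            fl = left | right
            rows.append({
                "dmr": k, "track": label,
                "inside_mean": float(lev[inside].mean()) if inside.any() else np.nan,
                "flank_mean": float(lev[fl].mean()) if fl.any() else np.nan,
                "n_inside": int(inside.sum()), "n_flank": int(fl.sum()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chromosome-level comparisons
# ---------------------------------------------------------------------------

def chromosome_mean_meth(stage_tracks: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome, per-stage mean methylation with pairwise stage tests.

    ``stage_tracks`` maps stage -> list of replicate tracks.  The first
    output holds the mean CpG level per (chromosome, stage, replicate); the
    second holds a Welch t-test per stage pair per chromosome, BH-adjusted
    across all tests.  With a single replicate per stage, only means are
    returned and the test table is empty.
    """
    rows = []
    for stage, tracks in stage_tracks.items():
        for r, t in enumerate(tracks):
            means = t.groupby("chrom")["level"].mean()
            for chrom, m in means.items():
                rows.append({"chrom": chrom, "stage": stage, "replicate": r,
                             "mean_meth": float(m)})
    means_df = pd.DataFrame(rows)

    tests = []
    stages = list(stage_tracks)
    if all(len(v) >= 2 for v in stage_tracks.values()):
        for chrom in sorted(means_df["chrom"].unique()):
            for s1, s2 in itertools.combinations(stages, 2):
                x = means_df.query("chrom == @chrom and stage == @s1")["mean_meth"]
                y = means_df.query("chrom == @chrom and stage == @s2")["mean_meth"]
                if x.std() == 0 and y.std() == 0:
                    p = 1.0 if x.mean() == y.mean() else 0.0
                else:
                    p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
                tests.append({"chrom": chrom, "stage_a": s1, "stage_b": s2,
                              "diff": float(x.mean() - y.mean()), "pvalue": p})
    tests_df = pd.DataFrame(tests)
    if len(tests_df):
        tests_df["qvalue"] = bh_adjust(tests_df["pvalue"].to_numpy())
    return means_df, tests_df


def segments_tile(segments, tol_bp: int = 0) -> bool:
    """True if per-chromosome segments are contiguous and non-overlapping."""
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, nxt in zip(segs, segs[1:]):
            if abs(nxt.start - prev.end) > tol_bp:
                return False
    return True
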