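"""Genomic interval infrastructure.

Gene models, the four-way feature annotation used throughout the pipeline
(upstream / gene body / downstream / distal, with the promoter defined as the
3 kb window upstream of the TSS), reproducibility-filtered consensus peaks,
CpG-island overlap and differential-accessibility summaries.

All coordinates are 0-based half-open internally; conversions to 1-based
conventions (GTF) happen only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PROMOTER_BP = 3000
DOWNSTREAM_BP = 3000

#: fine-grained feature precedence (ChIPseeker-like), highest first
_PRECEDENCE = ("promoter", "utr5", "utr3", "exon", "intron", "downstream", "distal")

#: collapse of fine features into the four-way categories
_COLLAPSE = {
    "promoter": "upstream",
    "utr5": "upstream",
    "exon": "gene_body",
    "intron": "gene_body",
    "utr3": "downstream",
    "downstream": "downstream",
    "distal": "distal",
}

CATEGORIES = ("upstream", "gene_body", "downstream", "distal")


class ParseError(ValueError):
    """Raised for malformed interval files; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS and optional sub-features.

    ``tss`` is the transcription start: ``start`` on the + strand, ``end - 1``
    on the - strand.  Exon/UTR lists are (start, end) pairs in the same
    0-based half-open convention.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = ()
    utr5: tuple = ()
    utr3: tuple = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.gene_id)

    def promoter(self, promoter_bp: int = PROMOTER_BP) -> GenomicInterval | None:
        """Strand-aware window of ``promoter_bp`` immediately upstream of the TSS."""
        if self.strand != "-":
            start, end = self.tss - promoter_bp, self.tss
        else:
            start, end = self.tss + 1, self.tss + 1 + promoter_bp
        start = max(0, start)
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end, self.strand, self.gene_id)

    def downstream_window(self, downstream_bp: int = DOWNSTREAM_BP) -> GenomicInterval:
        """Window of ``downstream_bp`` immediately past the gene end (strand-aware)."""
        if self.strand != "-":
            return GenomicInterval(self.chrom, self.end, self.end + downstream_bp,
                                   self.strand, self.gene_id)
        start = max(0, self.start - downstream_bp)
        return GenomicInterval(self.chrom, start, max(start + 1, self.start),
                               self.strand, self.gene_id)


@dataclass(frozen=True)
class PeakAnnotation:
    peak: GenomicInterval
    category: str
    nearest_gene: str
    dist_to_tss: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class DARRecord:
    region: GenomicInterval
    comparison: str
    log2_ratio: float
    pvalue: float
    fdr: float


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open, as on disk)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{i}: expected >=3 BED columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ParseError(f"{path}:{i}: non-integer coordinate") from e
            name = f[3] if len(f) > 3 else ""
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], start, end, strand, name, score))
    return out


def write_bed(path, intervals) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                     f"{iv.score:g}\t{iv.strand}\n")


def read_narrowpeak(path) -> list[GenomicInterval]:
    """Read ENCODE narrowPeak (10-column BED6+4); signalValue goes to ``score``."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(f"{path}:{i}: expected 10 narrowPeak columns, got {len(f)}")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]),
                                       f[5], f[3], float(f[6])))
    return out


def write_narrowpeak(path, intervals) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                     f"{iv.strand}\t{iv.score:g}\t-1\t-1\t-1\n")


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GTF (gene/exon/UTR features) or a TSV table.

    GTF coordinates (1-based closed) are converted to 0-based half-open.  The
    TSV dialect has a header line with at least gene_id, chrom, start, end,
    strand (already 0-based half-open).
    """
    path = str(path)
    if path.endswith((".gtf", ".gff")):
        return _read_gtf(path)
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    needed = ["gene_id", "chrom", "start", "end", "strand"]
    if all(k in cols for k in needed):
        return [
            GeneModel(str(r[cols["gene_id"]]), str(r[cols["chrom"]]),
                      int(r[cols["start"]]), int(r[cols["end"]]), str(r[cols["strand"]]))
            for _, r in df.iterrows()
        ]
    return _read_gtf(path)


def _read_gtf(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{i}: expected 9 GTF columns, got {len(f)}")
            chrom, _, feature, start, end, _, strand, _, attrs = f
            try:
                start0, end0 = int(start) - 1, int(end)  # 1-based closed -> half-open
            except ValueError as e:
                raise ParseError(f"{path}:{i}: non-integer coordinate") from e
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ParseError(f"{path}:{i}: missing gene_id attribute")
            rec = genes.setdefault(gid, {"chrom": chrom, "strand": strand,
                                         "start": None, "end": None,
                                         "exons": [], "utr5": [], "utr3": []})
            feat = feature.lower()
            if feat == "gene":
                rec["start"], rec["end"] = start0, end0
            elif feat == "exon":
                rec["exons"].append((start0, end0))
            elif feat in ("five_prime_utr", "5utr", "utr5"):
                rec["utr5"].append((start0, end0))
            elif feat in ("three_prime_utr", "3utr", "utr3"):
                rec["utr3"].append((start0, end0))
    out = []
    for gid, rec in genes.items():
        if rec["start"] is None:  # infer span from sub-features
            spans = rec["exons"] + rec["utr5"] + rec["utr3"]
            if not spans:
                continue
            rec["start"] = min(s for s, _ in spans)
            rec["end"] = max(e for _, e in spans)
        out.append(GeneModel(gid, rec["chrom"], rec["start"], rec["end"], rec["strand"],
                             tuple(sorted(rec["exons"])), tuple(sorted(rec["utr5"])),
                             tuple(sorted(rec["utr3"]))))
    return out


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key):
            return part[len(key):].strip().strip('"')
    return None


def write_gene_models_tsv(path, genes) -> None:
    pd.DataFrame(
        [{"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
          "end": g.end, "strand": g.strand} for g in genes]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------

def _fine_feature(mid: int, chrom: str, gene: GeneModel,
                  promoter_bp: int, downstream_bp: int) -> str | None:
    """Finest feature of ``gene`` containing the midpoint, or None."""
    if chrom != gene.chrom:
        return None
    prom = gene.promoter(promoter_bp)
    if prom is not None and prom.start <= mid < prom.end:
        return "promoter"
    for s, e in gene.utr5:
        if s <= mid < e:
            return "utr5"
    for s, e in gene.utr3:
        if s <= mid < e:
            return "utr3"
    if gene.start <= mid < gene.end:
        for s, e in gene.exons:
            if s <= mid < e:
                return "exon"
        return "intron"
    dw = gene.downstream_window(downstream_bp)
    if dw.start <= mid < dw.end:
        return "downstream"
    return None


def annotate_feature(peak: GenomicInterval, genes, promoter_bp: int = PROMOTER_BP,
                     downstream_bp: int = DOWNSTREAM_BP) -> PeakAnnotation:
    """Assign a peak to one of four genomic categories by its midpoint.

    The midpoint is matched against every gene's fine features in the order
    promoter > 5'UTR > 3'UTR > exon > intron > downstream; the winning fine
    feature is collapsed to upstream / gene_body / downstream, everything
    else is distal.  The nearest gene is chosen by absolute distance to the
    TSS (lexicographically smallest gene_id on ties).
    """
    mid = peak.midpoint
    best_feature = "distal"
    best_rank = _PRECEDENCE.index("distal")
    nearest, nearest_key = "", None
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        feat = _fine_feature(mid, peak.chrom, gene, promoter_bp, downstream_bp)
        if feat is not None:
            rank = _PRECEDENCE.index(feat)
            if rank < best_rank:
                best_rank, best_feature = rank, feat
        d = abs(mid - gene.tss)
        key = (d, gene.gene_id)
        if nearest_key is None or key < nearest_key:
            nearest_key, nearest = key, gene.gene_id
    if nearest_key is None:
        return PeakAnnotation(peak, "distal", "", 0)
    dist = _signed_tss_distance(mid, next(g for g in genes
                                          if g.gene_id == nearest and g.chrom == peak.chrom))
    return PeakAnnotation(peak, _COLLAPSE[best_feature], nearest, dist)


def _signed_tss_distance(mid: int, gene: GeneModel) -> int:
    """Signed distance to the TSS; positive in the direction of transcription."""
    d = mid - gene.tss
    return d if gene.strand != "-" else -d


def annotate_peaks(peaks, genes, promoter_bp: int = PROMOTER_BP,
                   downstream_bp: int = DOWNSTREAM_BP) -> list[PeakAnnotation]:
    return [annotate_feature(p, genes, promoter_bp, downstream_bp) for p in peaks]


# ---------------------------------------------------------------------------
# consensus peaks (reproducibility filter)
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, min_frac: float) -> bool:
    ov = a.overlap_len(b)
    if ov == 0:
        return False
    shorter = min(len(a), len(b))
    return ov >= min_frac * shorter


def consensus_peaks(replicate_sets, min_frac: float = 0.5) -> list[GenomicInterval]:
    """Reproducibility-filtered consensus of replicate peak sets.

    A deterministic stand-in for the IDR procedure: a peak of the first
    replicate is kept if it reciprocally overlaps (>= ``min_frac`` of the
    shorter interval) a peak in every other replicate; the reported consensus
    interval is the intersection of the matched cluster.  Externally computed
    IDR peaks in BED form can be used anywhere this output is consumed.
    """
    replicate_sets = [sorted(r, key=lambda p: (p.chrom, p.start)) for r in replicate_sets]
    if len(replicate_sets) < 2:
        raise ValueError("need >=2 replicates for a consensus")
    ref = replicate_sets[0]
    out = []
    for peak in ref:
        cluster = [peak]
        ok = True
        for other in replicate_sets[1:]:
            matches = [q for q in other if _reciprocal_overlap(peak, q, min_frac)]
            if not matches:
                ok = False
                break
            # best match = largest overlap
            cluster.append(max(matches, key=peak.overlap_len))
        if not ok:
            continue
        start = max(q.start for q in cluster)
        end = min(q.end for q in cluster)
        if start < end:
            out.append(replace(peak, start=start, end=end))
    return out


def cpg_island_overlap_fraction(peaks, islands) -> float:
    """Fraction of peaks sharing >=1 bp with any CpG island."""
    peaks = list(peaks)
    if not peaks:
        raise ValueError("overlap fraction undefined for an empty peak set")
    islands = list(islands)
    n = sum(1 for p in peaks if any(p.overlaps(i) for i in islands))
    return n / len(peaks)


# ---------------------------------------------------------------------------
# differential accessibility
# ---------------------------------------------------------------------------

def normalize_counts(counts: pd.DataFrame, method: str = "median_ratio") -> pd.DataFrame:
    """Normalize a region-by-sample count matrix across samples.

    ``median_ratio`` (default) divides each sample by the median ratio of
    its counts to the per-region geometric mean — robust when a minority of
    regions genuinely change, which would bias total-depth scaling.
    ``depth`` scales samples to the median library depth.
    """
    depth = counts.sum(axis=0)
    if (depth == 0).any():
        raise ValueError("sample with zero total counts")
    if method == "depth":
        return counts * (depth.median() / depth)
    logc = np.log(counts.where(counts > 0))
    ref = logc.mean(axis=1)
    usable = ref.notna()
    if not usable.any():
        return counts * (depth.median() / depth)
    ratios = logc.loc[usable].sub(ref[usable], axis=0)
    size = np.exp(ratios.median(axis=0))
    return counts / size


def differential_regions(counts: pd.DataFrame, group_a, group_b,
                         comparison: str = "", fdr_lt: float = 0.1,
                         regions: dict | None = None) -> list[DARRecord]:
    """Differential accessibility between two sample groups.

    A transparent stand-in for a negative-binomial model: counts are scaled
    to the median library depth, log2(x+1)-transformed, compared by Welch's t
    per region and BH-adjusted; regions with FDR < ``fdr_lt`` are reported.
    ``log2_ratio`` is the difference of group means of the log2 normalized
    counts (group_b minus group_a, i.e. later minus earlier).

    ``regions`` maps region ids (the index of ``counts``) to intervals; ids
    are parsed as "chrom:start-end" when absent.
    """
    norm = np.log2(normalize_counts(counts) + 1.0)
    a = norm[list(group_a)].to_numpy()
    b = norm[list(group_b)].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups
    fdr = bh_adjust(p)
    out = []
    for i, rid in enumerate(counts.index):
        if fdr[i] < fdr_lt:
            iv = (regions or {}).get(rid) or _parse_region_id(str(rid))
            out.append(DARRecord(iv, comparison, float(mean_b[i] - mean_a[i]),
                                 float(p[i]), float(fdr[i])))
    return out


def _parse_region_id(rid: str) -> GenomicInterval:
    try:
        chrom, span = rid.split(":")
        start, end = span.split("-")
        return GenomicInterval(chrom, int(start), int(end), name=rid)
    except Exception:
        return GenomicInterval("unknown", 0, 1, name=rid)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


@dataclass
class DARSummary:
    comparison: str
    n_dars: int
    decreased_fraction: float
    category_proportions: dict = field(default_factory=dict)


def dar_summary(dars, annotations) -> list[DARSummary]:
    """Per-comparison direction and four-way category breakdown of DARs.

    ``annotations`` aligns with ``dars`` index-wise (the annotation of each
    DAR's region).  Proportions over the four categories sum to 1 within each
    comparison.
    """
    dars = list(dars)
    annotations = list(annotations)
    if len(dars) != len(annotations):
        raise ValueError("dars and annotations must align")
    by_comp: dict[str, list[tuple[DARRecord, PeakAnnotation]]] = {}
    for d, a in zip(dars, annotations):
        by_comp.setdefault(d.comparison, []).append((d, a))
    out = []
    for comp, pairs in sorted(by_comp.items()):
        n = len(pairs)
        dec = sum(1 for d, _ in pairs if d.log2_ratio < 0) / n
        props = {c: sum(1 for _, a in pairs if a.category == c) / n for c in CATEGORIES}
        out.append(DARSummary(comp, n, dec, props))
    return out
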