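"""Cross-layer integration of accessibility, methylation and expression.

Sign-consistency between differentially accessible regions and DEGs,
DMR-regulated genes, the TSS+-3kb interaction classes (open chromatin only /
methylation only / both), the LMR-expression correlation, the slow-fiber
correlate screen and a generic hypergeometric over-representation test on
user-supplied gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import bh_adjust
from .stratify import spearman_phenotype

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# DAR-DEG sign consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistentPair:
    gene: str
    comparison: str
    dar_log2: float
    deg_log2: float
    facet: str          # the DAR's four-way category
    direction: str      # co_up | co_down


def dar_deg_consistency(annotated_dars, deg_table: pd.DataFrame
                        ) -> tuple[list[ConsistentPair], pd.DataFrame]:
    """Pairs of (DAR, DEG) sharing the same nonzero fold-change sign.

    ``annotated_dars`` is an iterable of (DARRecord, PeakAnnotation); the
    DEG table is matched on (nearest gene, comparison).  A gene with several
    DARs yields several pairs.  Also returns quadrant counts per facet per
    comparison (co_up ~ first quadrant, co_down ~ third).
    """
    deg = deg_table.set_index(["gene", "comparison"])
    pairs = []
    for dar, ann in annotated_dars:
        key = (ann.nearest_gene, dar.comparison)
        if key not in deg.index:
            continue
        rows = deg.loc[[key]]
        for _, r in rows.iterrows():
            s1, s2 = np.sign(dar.log2_ratio), np.sign(r["log2fc"])
            if s1 == 0 or s2 == 0 or s1 != s2:
                continue
            pairs.append(ConsistentPair(
                ann.nearest_gene, dar.comparison, float(dar.log2_ratio),
                float(r["log2fc"]), ann.category,
                "co_up" if s1 > 0 else "co_down"))
    counts = (pd.DataFrame([p.__dict__ for p in pairs])
              .groupby(["comparison", "facet", "direction"]).size()
              .rename("n").reset_index()
              if pairs else
              pd.DataFrame(columns=["comparison", "facet", "direction", "n"]))
    return pairs, counts


def dmr_regulated_genes(dmr_host_genes, deg_universe) -> set:
    """Genes hosting a DMR that are also differentially expressed."""
    return set(dmr_host_genes) & set(deg_universe)


# ---------------------------------------------------------------------------
# TSS+-3kb interaction classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethSiteRule:
    """What counts as a methylated site inside the TSS window.

    A CpG is methylation evidence if covered by >= ``min_coverage`` reads at
    a level >= ``min_level`` — this keeps unmethylated CpG-island positions
    from counting as evidence of methylation.
    """
    min_coverage: int = 5
    min_level: float = 0.5


def tss_window_classes(genes, peaks, track: pd.DataFrame, window_bp: int = 3000,
                       rule: MethSiteRule | None = None) -> pd.DataFrame:
    """Classify genes by TSS+-window evidence: idr_only / meth_only / both.

    A gene has open-chromatin (IDR) evidence if any consensus peak overlaps
    [tss - window, tss + window]; methylation evidence if >= 1 CpG in the
    window passes ``rule``.  Genes with neither are left out of the classes
    (reported as "none" rows for bookkeeping).  The window is symmetric
    regardless of strand.
    """
    rule = rule or MethSiteRule()
    peak_list = list(peaks)
    rows = []
    for g in genes:
        lo, hi = g.tss - window_bp, g.tss + window_bp + 1
        has_peak = any(p.chrom == g.chrom and p.start < hi and lo < p.end
                       for p in peak_list)
        sub = track[(track["chrom"] == g.chrom)
                    & (track["pos"] - 1 >= lo) & (track["pos"] - 1 < hi)]
        qualifying = ((sub["meth"] + sub["unmeth"] >= rule.min_coverage)
                      & (sub["level"] >= rule.min_level))
        has_meth = bool(qualifying.any())
        if has_peak and has_meth:
            klass = "both"
        elif has_peak:
            klass = "idr_only"
        elif has_meth:
            klass = "meth_only"
        else:
            klass = "none"
        rows.append({"gene": g.gene_id, "klass": klass})
    return pd.DataFrame(rows).set_index("gene")


def venn_counts(classes: pd.DataFrame) -> dict[str, int]:
    c = classes["klass"].value_counts()
    return {k: int(c.get(k, 0)) for k in ("idr_only", "meth_only", "both", "none")}


def class_expression_contrast(classes: pd.DataFrame, expr_stage_mean: pd.Series
                              ) -> pd.DataFrame:
    """Median stage expression per interaction class, with the ordering noted.

    Reports median(idr_only), median(both), median(meth_only) and whether
    median(idr_only) >= median(both) >= median(meth_only).  Nothing is
    enforced — the ordering is an observation, not a constraint.
    """
    rows = []
    for klass in ("idr_only", "both", "meth_only"):
        members = classes.index[classes["klass"] == klass]
        vals = expr_stage_mean.reindex(members).dropna()
        if len(vals) == 0:
            logger.info("class %s empty; skipped", klass)
            rows.append({"klass": klass, "n": 0, "median": np.nan})
            continue
        rows.append({"klass": klass, "n": len(vals), "median": float(vals.median())})
    df = pd.DataFrame(rows).set_index("klass")
    med = df["median"]
    df.attrs["ordering_holds"] = bool(
        np.all(np.isfinite(med.to_numpy()))
        and med["idr_only"] >= med["both"] >= med["meth_only"])
    return df


# ---------------------------------------------------------------------------
# LMR-expression correlation
# ---------------------------------------------------------------------------

def lmr_expression_correlation(lmr_meth: pd.Series, host_expr: pd.Series
                               ) -> tuple[float, float]:
    """Spearman rho between LMR median methylation and host-gene expression.

    Inputs align index-wise (one entry per LMR with an expressed host gene).
    Returns (rho, two-sided p).
    """
    x = lmr_meth.to_numpy(dtype=float)
    y = host_expr.to_numpy(dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >=3 paired observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# slow-fiber correlate screen
# ---------------------------------------------------------------------------

def slow_fiber_correlates(expr: pd.DataFrame, slow_fraction: pd.Series,
                          rho_abs_gt: float = 0.7, p_lt: float = 0.05,
                          baseline_stage: str = "D3") -> pd.DataFrame:
    """Genes whose expression tracks the slow-twitch fiber proportion.

    Spearman rho per gene against the per-sample phenotype; genes pass with
    |rho| strictly above ``rho_abs_gt`` and p strictly below ``p_lt``.  The
    output carries rho and the baseline-stage mean expression.
    """
    cor = spearman_phenotype(expr, slow_fraction)
    base_cols = [c for c in expr.columns if str(c).startswith(f"{baseline_stage}_")]
    baseline = expr[base_cols].mean(axis=1) if base_cols else pd.Series(np.nan,
                                                                        index=expr.index)
    keep = cor[(cor["rho"].abs() > rho_abs_gt) & (cor["pvalue"] < p_lt)].copy()
    keep["baseline_expr"] = baseline.reindex(keep.index)
    return keep.sort_values("rho")


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORAResult:
    term_id: str
    k: int
    K: int
    n: int
    N: int
    pvalue: float
    qvalue: float


def read_gmt(path) -> dict[str, set]:
    """GMT gene-set file: term <tab> description <tab> gene1 <tab> ..."""
    terms = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            terms[f[0]] = set(g for g in f[2:] if g)
    return terms


def ora_hypergeometric(gene_set, universe, gmt_terms: dict,
                       q_lt: float | None = None) -> list[ORAResult]:
    """Upper-tail hypergeometric over-representation with BH correction.

    For each term: p = P(X >= k) with X ~ Hypergeom(N=|universe|,
    K=|term ∩ universe|, n=|gene_set|).  The gene set must lie inside the
    universe; terms are intersected with it.  Results are sorted by q-value;
    with ``q_lt`` set, only passing terms are returned.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    N, n = len(universe), len(gene_set)
    names, pvals, kk, KK = [], [], [], []
    for term, members in gmt_terms.items():
        K = len(members & universe)
        if K == 0:
            continue
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        names.append(term)
        pvals.append(min(1.0, p))
        kk.append(k)
        KK.append(K)
    q = bh_adjust(pvals)
    out = [ORAResult(t, k, K, n, N, p, float(qv))
           for t, k, K, p, qv in zip(names, kk, KK, pvals, q)]
    out.sort(key=lambda r: (r.qvalue, r.pvalue, r.term_id))
    if q_lt is not None:
        out = [r for r in out if r.qvalue < q_lt]
    return out
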