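"""Phenotype-correlated stratification of differentially expressed genes.

DEGs are selected per stage pair, correlated gene-by-gene with the
cross-sectional-area (CSA) phenotype by Spearman's rho, clustered on the
1-D rho axis by a self-organizing map whose codebook is then split into two
groups (G1/G2) by hierarchical clustering, and each group's z-scored stage
profiles are partitioned into three temporal tendencies by fuzzy c-means:

* T1 — rise then fall (peak at an intermediate stage),
* T2 — monotone increase across stages,
* T3 — fall then rise (the mirror image of T1).

Expression is assumed to be on a variance-stabilized scale (log2 CPM with a
pseudocount of 1); the differential test shipped here (Welch's t + BH) is a
stand-in used for synthetic data — externally computed DEG tables are
accepted unchanged.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .regions import bh_adjust

logger = logging.getLogger(__name__)

STAGES = ("D3", "M3", "M6", "M12")

TENDENCIES = ("T1", "T2", "T3")

#: canonical z-scorable stage-profile shapes used to name FCM centroids
TENDENCY_TEMPLATES = {
    "T1": np.array([0.0, 2.0, 1.0, -1.0]),
    "T2": np.array([-1.5, -0.5, 0.5, 1.5]),
    "T3": np.array([0.0, -2.0, -1.0, 1.0]),
}


def stage_pairs(stages=STAGES) -> list[str]:
    """The six unordered stage pairs, as "EARLIER-LATER" strings."""
    return [f"{a}-{b}" for a, b in itertools.combinations(stages, 2)]


# ---------------------------------------------------------------------------
# DEG selection and overlap bookkeeping
# ---------------------------------------------------------------------------

def select_degs(deg_table: pd.DataFrame, lfc_gt: float = 0.0,
                q_lt: float = 0.05) -> tuple[dict[str, set], set]:
    """Select DEGs per comparison with strict |log2FC| > lfc_gt and q < q_lt.

    Returns (per-comparison gene sets, union across comparisons).  Both
    inequalities are strict, so a gene at exactly q = 0.05 or log2FC = 0 is
    excluded.
    """
    per_comp: dict[str, set] = {}
    mask = (deg_table["log2fc"].abs() > lfc_gt) & (deg_table["qvalue"] < q_lt)
    for comp, sub in deg_table.loc[mask].groupby("comparison"):
        per_comp[str(comp)] = set(sub["gene"])
    union = set().union(*per_comp.values()) if per_comp else set()
    return per_comp, union


def overlap_stats(sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise and triple intersection counts with percentage shares.

    The share of an intersection is reported relative to the union of the
    participating sets, as 100 * |intersection| / |union| rounded to one
    decimal.
    """
    if len(sets) < 2:
        raise ValueError("need >=2 named sets")
    rows = []
    names = sorted(sets)
    for r in (2, 3):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            union = set.union(*(sets[n] for n in combo))
            if not union:
                raise ValueError(f"share undefined: empty union for {combo}")
            rows.append({
                "sets": "&".join(combo), "k": r,
                "intersection": len(inter), "union": len(union),
                "share_pct": overlap_share(len(inter), len(union)),
            })
    return pd.DataFrame(rows)


def overlap_share(n_intersection: int, n_reference: int) -> float:
    """Percentage share 100*k/n rounded to one decimal (e.g. 3066/5535 -> 55.4)."""
    if n_reference == 0:
        raise ValueError("share undefined for an empty reference set")
    return round(100.0 * n_intersection / n_reference, 1)


def log2fc_to_fold(lfc: float) -> float:
    """Linear fold change from a log2 fold change (2.5 -> 5.7)."""
    if not math.isfinite(lfc):
        raise ValueError("log2 fold change must be finite")
    return 2.0 ** lfc


# ---------------------------------------------------------------------------
# Spearman correlation with the CSA phenotype
# ---------------------------------------------------------------------------

def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p for Spearman's rho at small n."""
    base = np.arange(1, n + 1, dtype=float)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(base):
        r = np.corrcoef(base, perm)[0, 1]
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman_phenotype(expr: pd.DataFrame, phenotype: pd.Series,
                       exact_n_max: int = 8) -> pd.DataFrame:
    """Spearman rho of each gene's expression against a per-sample phenotype.

    Ties are midranked.  The two-sided p-value is an exact permutation
    enumeration for n <= ``exact_n_max`` samples, otherwise the usual
    t-approximation.  Genes with constant expression have undefined rho and
    are flagged (rho = NaN) so callers can exclude them.
    """
    common = [s for s in expr.columns if s in phenotype.index]
    if len(common) < 3:
        raise ValueError("need >=3 aligned samples")
    x = expr[common].to_numpy(dtype=float)
    y = phenotype[common].to_numpy(dtype=float)
    n = len(common)
    records = []
    y_rank = stats.rankdata(y)
    for gi, gene in enumerate(expr.index):
        row = x[gi]
        if np.ptp(row) == 0:
            records.append({"gene": gene, "rho": np.nan, "pvalue": np.nan})
            continue
        r_rank = stats.rankdata(row)
        rho = float(np.corrcoef(r_rank, y_rank)[0, 1])
        if n <= exact_n_max:
            p = _spearman_exact_p(rho, n)
        else:
            t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        records.append({"gene": gene, "rho": rho, "pvalue": min(1.0, p)})
    return pd.DataFrame(records).set_index("gene")


# ---------------------------------------------------------------------------
# 1-D self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SOMModel:
    grid_shape: tuple
    codebook: np.ndarray          # one scalar weight per node
    bmu: np.ndarray               # node index per input
    inputs: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.grid_shape))


def fit_som_1d(values, grid_shape=(8, 1), epochs: int = 100, lr0: float = 0.5,
               lr_end: float = 0.01, sigma0: float = 4.0, sigma_end: float = 0.5,
               seed: int = 0) -> SOMModel:
    """Fit a small self-organizing map to scalar inputs (here: rho values).

    Online training: for each presented value, the best-matching unit (BMU,
    nearest codebook weight, ties to the lowest node index) and its grid
    neighbours are pulled toward the value with a Gaussian neighbourhood;
    learning rate and neighbourhood width decay linearly over epochs.  The
    codebook is initialized from evenly spaced quantiles of the input so the
    map spans the data from the start.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite inputs must be filtered upstream")
    rng = np.random.default_rng(seed)
    n_nodes = int(np.prod(grid_shape))
    grid_pos = np.array([(i // grid_shape[1], i % grid_shape[1])
                         for i in range(n_nodes)], dtype=float)
    codebook = np.quantile(x, np.linspace(0, 1, n_nodes)) if x.size else np.zeros(n_nodes)
    codebook = codebook.astype(float)

    for epoch in range(epochs):
        frac = epoch / max(1, epochs - 1)
        lr = lr0 + (lr_end - lr0) * frac
        sigma = sigma0 + (sigma_end - sigma0) * frac
        order = rng.permutation(x.size)
        for i in order:
            v = x[i]
            bmu = int(np.argmin(np.abs(codebook - v)))  # argmin takes lowest on ties
            d2 = ((grid_pos - grid_pos[bmu]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2.0 * sigma * sigma))
            codebook += lr * h * (v - codebook)

    bmu = np.array([int(np.argmin(np.abs(codebook - v))) for v in x])
    return SOMModel(tuple(grid_shape), codebook, bmu, inputs=x)


def split_two_groups(som: SOMModel, linkage_method: str = "complete") -> np.ndarray:
    """Split SOM nodes into two groups; genes inherit their BMU's group.

    The codebook weights are clustered agglomeratively (complete linkage,
    Euclidean) and cut at k=2; the group with the higher mean input value is
    labeled G1 by convention.  Returns an array of "G1"/"G2" per input.
    """
    w = som.codebook
    if np.unique(w).size < 2:
        raise ValueError("degenerate codebook: fewer than 2 distinct weights")
    Z = linkage(w.reshape(-1, 1), method=linkage_method, metric="euclidean")
    node_cluster = fcluster(Z, t=2, criterion="maxclust")
    gene_cluster = node_cluster[som.bmu]
    means = {c: som.inputs[gene_cluster == c].mean()
             for c in np.unique(gene_cluster) if (gene_cluster == c).any()}
    if len(means) < 2:  # all genes in one node cluster; fall back to node means
        means = {c: w[node_cluster == c].mean() for c in np.unique(node_cluster)}
    g1 = max(means, key=means.get)
    return np.where(gene_cluster == g1, "G1", "G2")


# ---------------------------------------------------------------------------
# fuzzy c-means over stage profiles
# ---------------------------------------------------------------------------

@dataclass
class FuzzyCMeansResult:
    centroids: np.ndarray         # (c, n_stages)
    memberships: np.ndarray       # (n_genes, c), rows sum to 1
    labels: np.ndarray            # argmax cluster per gene
    objective: list               # J_m per iteration
    tendency_of_cluster: dict     # cluster index -> T1/T2/T3


def zscore_profiles(stage_means: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene's stage-mean profile to mean 0, SD 1."""
    v = stage_means.to_numpy(dtype=float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant stage profile cannot be standardized")
    return pd.DataFrame((v - mu) / sd, index=stage_means.index,
                        columns=stage_means.columns)


def fuzzy_cmeans(profiles: pd.DataFrame, c: int = 3, m: float = 2.0,
                 tol: float = 1e-6, max_iter: int = 300,
                 seed: int = 0) -> FuzzyCMeansResult:
    """Fuzzy c-means on z-scored stage profiles, with tendency naming.

    Standard alternating updates: memberships
    u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)) and weighted centroids
    v_i = sum_j u_ij^m x_j / sum_j u_ij^m, iterated until the largest
    membership change is below ``tol``.  A point coinciding with a centroid
    receives membership 1 for that cluster (the d -> 0 limit).  Clusters are
    named T1/T2/T3 by correlating centroids with the canonical shape
    templates and taking the best one-to-one assignment.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(c), size=n)  # random fuzzy init
    objective = []
    for _ in range(max_iter):
        um = u ** m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        objective.append(float((um * d2).sum()))
        u_new = _fcm_memberships(d2, m)
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            break
    um = u ** m
    centroids = (um.T @ x) / um.sum(axis=0)[:, None]
    labels = u.argmax(axis=1)
    tendency = _name_clusters(centroids)
    return FuzzyCMeansResult(centroids, u, labels, objective, tendency)


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    n, c = d2.shape
    u = np.zeros((n, c))
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-power)
    u[~any_zero] = inv[~any_zero] / inv[~any_zero].sum(axis=1, keepdims=True)
    for i in np.where(any_zero)[0]:
        u[i] = zero[i] / zero[i].sum()
    return u


def _name_clusters(centroids: np.ndarray) -> dict[int, str]:
    names = list(TENDENCY_TEMPLATES)
    cost = np.zeros((centroids.shape[0], len(names)))
    for i, cen in enumerate(centroids):
        for j, nm in enumerate(names):
            t = TENDENCY_TEMPLATES[nm]
            cost[i, j] = -np.corrcoef(cen, t)[0, 1]
    rows, cols = linear_sum_assignment(cost)
    return {int(r): names[c] for r, c in zip(rows, cols)}


def assign_tendencies(expr: pd.DataFrame, groups: pd.Series, stages=STAGES,
                      c: int = 3, m: float = 2.0, seed: int = 0) -> pd.DataFrame:
    """Per-group FCM over z-scored stage means; returns the assignment table.

    ``groups`` maps gene -> G1/G2.  Output columns: group, tendency, m1..m3
    (memberships in T1..T3 order).
    """
    stage_means = stage_mean_matrix(expr, stages)
    rows = []
    for gname in sorted(groups.unique()):
        genes = groups.index[groups == gname]
        prof = zscore_profiles(stage_means.loc[genes])
        fit = fuzzy_cmeans(prof, c=c, m=m, seed=seed)
        order = {t: k for k, t in fit.tendency_of_cluster.items()}
        for gi, gene in enumerate(prof.index):
            mem = {f"m{j + 1}": float(fit.memberships[gi, order[t]])
                   for j, t in enumerate(TENDENCIES)}
            rows.append({"gene": gene, "group": gname,
                         "tendency": fit.tendency_of_cluster[int(fit.labels[gi])],
                         **mem})
    return pd.DataFrame(rows).set_index("gene")


def stage_mean_matrix(expr: pd.DataFrame, stages=STAGES) -> pd.DataFrame:
    """Collapse replicate columns ("STAGE_rN" or "STAGE.N") to stage means."""
    cols = {}
    for s in stages:
        members = [c for c in expr.columns if str(c) == s or str(c).startswith(f"{s}_")
                   or str(c).startswith(f"{s}.")]
        if not members:
            raise ValueError(f"no samples found for stage {s}")
        cols[s] = expr[members].mean(axis=1)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# stand-in differential test for synthetic data
# ---------------------------------------------------------------------------

def welch_deg_table(expr: pd.DataFrame, stages=STAGES) -> pd.DataFrame:
    """Per-pair Welch t-test on replicate columns with BH adjustment.

    A stand-in differential test on the log2 scale for synthetic matrices;
    log2fc is the difference of stage means (later minus earlier).  Real
    differential tables are accepted by the rest of the pipeline unchanged.
    """
    frames = []
    for a, b in itertools.combinations(stages, 2):
        xa = expr[[c for c in expr.columns if str(c).startswith(f"{a}_")]].to_numpy()
        xb = expr[[c for c in expr.columns if str(c).startswith(f"{b}_")]].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        frames.append(pd.DataFrame({
            "gene": expr.index, "comparison": f"{a}-{b}",
            "log2fc": xb.mean(axis=1) - xa.mean(axis=1),
            "pvalue": p, "qvalue": bh_adjust(p),
        }))
    return pd.concat(frames, ignore_index=True)
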