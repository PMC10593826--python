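"""PWM motif scanning and TF-target network assembly.

De novo motif discovery is out of scope; instead, user-supplied position
weight matrices (MEME minimal format) are scanned over peak or LMR
sequences with log-odds scoring on both strands.  TFs whose motifs hit a
regulatory region are validated against the expression matrix and connected
to candidate target genes through an external TF-target edge table
(hTFtarget-like TSV), yielding the open-chromatin (IDR) and LMR networks
and the fiber-type metabolic subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    tf_name: str
    matrix: np.ndarray                      # 4 x L probabilities (rows ACGT)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.tf_name}: columns must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """Log-odds score matrix in bits.

        score(b, i) = log2(((p_ib + pseudocount * bg_b) / (1 + pseudocount))
        / bg_b); the pseudocount keeps zero probabilities finite.
        """
        p = (self.matrix + self.pseudocount * self.background[:, None]) \
            / (1.0 + self.pseudocount)
        return np.log2(p / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    tf: str
    offset: int      # 0-based position of the leftmost base on the + strand
    strand: str
    score: float


# ---------------------------------------------------------------------------
# MEME minimal IO
# ---------------------------------------------------------------------------

def read_meme(path) -> list[PWM]:
    pwms = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            f = lines[i + 1].split()
            background = np.array([float(f[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                j += 1
            width = None
            for tok1, tok2 in zip(lines[j].split(), lines[j].split()[1:]):
                if tok1 == "w=":
                    width = int(tok2)
            rows = []
            k = j + 1
            while k < len(lines) and lines[k].strip() and not lines[k].startswith("MOTIF"):
                rows.append([float(v) for v in lines[k].split()])
                k += 1
            mat = np.array(rows).T  # file is L x 4 -> 4 x L
            if width is not None and mat.shape[1] != width:
                raise ValueError(f"motif {name}: stated width {width} != {mat.shape[1]}")
            pwms.append(PWM(name, mat, background.copy()))
            i = k
            continue
        i += 1
    return pwms


def write_meme(path, pwms) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write("A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg))
        for p in pwms:
            fh.write(f"MOTIF {p.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} "
                     f"nsites= 20 E= 0\n")
            for col in p.matrix.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Sequence to row indices; ambiguous bases become -1 (scored 0)."""
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _score_windows(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; ambiguous bases contribute 0."""
    L = lod.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i in range(L):
        col = codes[i:i + n]
        valid = col >= 0
        scores[valid] += lod[col[valid], i]
    return scores


def scan_motifs(sequences: dict, pwm: PWM,
                min_score_bits: float | None = None) -> list[MotifHit]:
    """Scan both strands of every sequence for PWM matches.

    A minus-strand hit is reported at the + strand coordinate of its
    leftmost base.  ``min_score_bits`` defaults to 80% of the maximal
    attainable score.  Hits are sorted by (seq_id, offset, strand).
    """
    if min_score_bits is None:
        min_score_bits = 0.8 * pwm.max_score()
    lod = pwm.log_odds()
    L = len(pwm)
    hits = []
    for sid in sorted(sequences):
        seq = str(sequences[sid])
        if L > len(seq):
            continue
        fwd = _score_windows(_encode(seq), lod)
        rev = _score_windows(_encode(reverse_complement(seq)), lod)
        n = len(seq) - L + 1
        for off in range(n):
            if fwd[off] >= min_score_bits:
                hits.append(MotifHit(sid, pwm.tf_name, off, "+", float(fwd[off])))
            # window at rc-offset k covers + strand bases [n-1-k, n-1-k+L)
            r = n - 1 - off
            if rev[r] >= min_score_bits:
                hits.append(MotifHit(sid, pwm.tf_name, off, "-", float(rev[r])))
    hits.sort(key=lambda h: (h.seq_id, h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# TF validation and network assembly
# ---------------------------------------------------------------------------

def validate_tf_expression(tf_names, expr_stage_means: pd.DataFrame,
                           min_expr: float = 1.0,
                           deg_universe: set | None = None,
                           alias: dict | None = None) -> dict[str, list]:
    """Validate motif TFs against the expression matrix, per stage.

    A TF is validated in a stage when its stage-mean expression is
    >= ``min_expr`` (log2 CPM) and, when ``deg_universe`` is given, the TF
    is itself differentially expressed.  TF names resolve to gene ids
    case-insensitively, optionally through an alias map; unresolvable names
    are excluded with a log message.
    """
    alias = {k.upper(): v for k, v in (alias or {}).items()}
    index_by_upper = {str(g).upper(): g for g in expr_stage_means.index}
    out: dict[str, list] = {}
    for tf in tf_names:
        key = alias.get(tf.upper(), tf)
        gene = index_by_upper.get(str(key).upper())
        if gene is None:
            logger.info("TF %s not resolvable in the expression matrix", tf)
            continue
        if deg_universe is not None and gene not in deg_universe:
            out[tf] = []
            continue
        stages = [s for s in expr_stage_means.columns
                  if expr_stage_means.loc[gene, s] >= min_expr]
        out[tf] = stages
    return out


@dataclass
class Network:
    source: str                      # idr | lmr
    edges: list                      # (tf, target, stage) tuples

    @property
    def tfs(self) -> set:
        return {e[0] for e in self.edges}

    @property
    def targets(self) -> set:
        return {e[1] for e in self.edges}

    def summary(self) -> dict:
        """Counts of TFs, targets and unique TF-target pairs (stage-collapsed)."""
        return {"source": self.source, "n_tf": len(self.tfs),
                "n_target": len(self.targets),
                "n_edge": len({(tf, t) for tf, t, _ in self.edges})}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["tf", "target", "stage"])


def build_network(validated_tfs: dict, candidate_targets,
                  edge_table: pd.DataFrame, source: str) -> Network:
    """Connect validated TFs to candidate targets through the edge table.

    Edges are exactly the (tf, target) rows of the edge table whose TF is
    validated (in >= 1 stage) and whose target is a candidate — the network
    never invents an edge.  Matching is case-insensitive; per-edge stage
    provenance is the validated stages of the TF.
    """
    if edge_table.empty:
        logger.warning("empty edge table: returning an empty %s network", source)
        return Network(source, [])
    cand = {str(t).upper() for t in candidate_targets}
    valid = {tf.upper(): stages for tf, stages in validated_tfs.items() if stages}
    edges = []
    for _, row in edge_table.iterrows():
        tf, target = str(row["tf"]), str(row["target"])
        stages = valid.get(tf.upper())
        if stages is None or target.upper() not in cand:
            continue
        for s in stages:
            edges.append((tf, target, s))
    return Network(source, sorted(set(edges)))


def fiber_type_subnetwork(network: Network, metabolic_genes,
                          slow_fiber_correlates) -> Network:
    """Restrict targets to metabolic, slow-fiber-correlated genes.

    Keeps edges whose target lies in the intersection of the metabolic gene
    list and the slow-fiber correlate list; TFs keeping >= 1 edge remain.
    """
    allowed = {str(g).upper() for g in metabolic_genes} \
        & {str(g).upper() for g in slow_fiber_correlates}
    edges = [e for e in network.edges if e[1].upper() in allowed]
    if not edges:
        logger.warning("fiber-type subnetwork is empty")
    return Network(f"{network.source}_fiber_type", edges)


def read_edge_table(path) -> pd.DataFrame:
    """TF-target TSV with >= 2 columns (tf, target, evidence...)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "tf" not in cols or "target" not in cols:
        df = pd.read_csv(path, sep="\t", header=None)
        df = df.rename(columns={0: "tf", 1: "target"})
    else:
        df = df.rename(columns={cols["tf"]: "tf", cols["target"]: "target"})
    return df
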