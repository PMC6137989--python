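"""Input-normalized metagene matrices, quintile stratification and pattern
clustering.

The bin grid is 50 fixed upstream bins (1 kb, 20 bp each), 100 scaled
gene-body bins and 50 fixed downstream bins; minus-strand rows are
reversed so the TSS is always on the left.  Per-bin values are
log2((chip_density + c) / (control_density + c)) where densities are
library-scaled counts per bp and ``c`` is a pseudocount applied as counts
per bin before the density conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io import CoverageTrack, ExpressionTable, GeneModel

logger = logging.getLogger(__name__)

N_FLANK_BINS = 50
N_BODY_BINS = 100
FLANK_BP = 1000
N_BINS = 2 * N_FLANK_BINS + N_BODY_BINS

BODY = slice(N_FLANK_BINS, N_FLANK_BINS + N_BODY_BINS)
# shape-rule zones used only for semantic labelling of k-means centroids
_BODY_CORE = slice(75, 150)
_TSS_ZONE = slice(38, 75)

__all__ = [
    "MetaprofileMatrix",
    "QuintileAssignment",
    "PatternClusters",
    "build_matrix",
    "average_profile",
    "assign_quintiles",
    "cluster_patterns",
    "replicate_concordance",
]


@dataclass
class MetaprofileMatrix:
    gene_ids: list[str]
    values: np.ndarray  # n_genes x N_BINS
    pseudocount: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), N_BINS):
            raise ValueError("matrix shape does not match gene list / bin grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")

    def rows(self, gene_subset) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        return self.values[[index[g] for g in gene_subset]]


@dataclass
class QuintileAssignment:
    assignments: dict[str, str]  # gene_id -> Q0..Q5
    q0_sub: dict[str, str] = field(default_factory=dict)  # gene_id -> Q0a/Q0b

    def genes_in(self, label: str) -> list[str]:
        if label in ("Q0a", "Q0b"):
            return sorted(g for g, l in self.q0_sub.items() if l == label)
        return sorted(g for g, l in self.assignments.items() if l == label)


@dataclass
class PatternClusters:
    assignments: dict[str, str]  # gene_id -> k1/k2/k3 (or cluster_<i>)
    centroids: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)  # k -> semantic label

    def genes_in(self, cluster: str) -> list[str]:
        return sorted(g for g, c in self.assignments.items() if c == cluster)


def _bin_sums(vec: np.ndarray, window: int, edges: np.ndarray) -> np.ndarray:
    """bp-weighted window-count sums over [edges[i], edges[i+1]) intervals.

    The per-bp density within a window is count/window; the cumulative count
    F(x) is piecewise linear, so a bin sum is F(b) - F(a).  Coordinates
    outside the chromosome contribute zero.
    """
    chrom_len = vec.size * window
    x = np.clip(edges.astype(float), 0, chrom_len)
    prefix = np.concatenate([[0.0], np.cumsum(vec)])
    widx = np.minimum((x // window).astype(int), vec.size - 1)
    f = prefix[widx] + vec[widx] * (x - widx * window) / window
    f = np.where(x >= chrom_len, prefix[-1], f)
    return np.diff(f)


def _gene_bin_edges(gene: GeneModel) -> np.ndarray:
    """Genome-order bin edges from start-1kb to end+1kb (200 bins)."""
    left = np.linspace(gene.start - FLANK_BP, gene.start, N_FLANK_BINS + 1)
    body = np.linspace(gene.start, gene.end, N_BODY_BINS + 1)
    right = np.linspace(gene.end, gene.end + FLANK_BP, N_FLANK_BINS + 1)
    return np.concatenate([left[:-1], body[:-1], right])


def build_matrix(chip: CoverageTrack, control: CoverageTrack,
                 genes: list[GeneModel], pseudocount: float = 0.5) -> MetaprofileMatrix:
    """Genes x bins matrix of log2 chip/control density ratios."""
    if not genes:
        raise ValueError("need at least one gene")
    if not chip.same_grid(control):
        raise ValueError("tracks are not on the same window grid")
    chip_lib, ctrl_lib = chip.library_size, control.library_size
    if chip_lib <= 0 or ctrl_lib <= 0:
        raise ValueError("both libraries must have positive depth")

    widths_flank = np.full(N_FLANK_BINS, FLANK_BP / N_FLANK_BINS)
    values = np.empty((len(genes), N_BINS))
    for i, gene in enumerate(genes):
        edges = _gene_bin_edges(gene)
        if edges[0] < 0 or edges[-1] > chip.chrom_length(gene.chrom):
            logger.warning("%s: flank extends outside chromosome; row clipped",
                           gene.gene_id)
        widths = np.concatenate([
            widths_flank, np.full(N_BODY_BINS, gene.length / N_BODY_BINS), widths_flank,
        ])
        c_raw = _bin_sums(chip.counts[gene.chrom], chip.window_size, edges)
        i_raw = _bin_sums(control.counts[gene.chrom], control.window_size, edges)
        dc = (c_raw + pseudocount) / (widths * chip_lib)
        di = (i_raw + pseudocount) / (widths * ctrl_lib)
        row = np.log2(dc / di)
        if gene.strand == "-":
            row = row[::-1]
        values[i] = row
    return MetaprofileMatrix([g.gene_id for g in genes], values, pseudocount)


def average_profile(matrix: MetaprofileMatrix, gene_subset) -> tuple[np.ndarray, np.ndarray]:
    """Column means and standard errors over a gene subset."""
    subset = list(gene_subset)
    if not subset:
        raise ValueError("gene subset is empty")
    rows = matrix.rows(subset)
    mean = rows.mean(axis=0)
    se = rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0]) if rows.shape[0] > 1 \
        else np.zeros(N_BINS)
    return mean, se


def assign_quintiles(expr: ExpressionTable, fpkm: pd.DataFrame, condition: str,
                     matrix: MetaprofileMatrix | None = None,
                     seed: int = 0) -> QuintileAssignment:
    """Rank genes by replicate-mean FPKM into Q1 (highest) .. Q5; Q0 = FPKM 0.

    Expressed genes (mean FPKM > 0) are ranked descending with ties broken
    by gene_id and split into five bins whose sizes differ by at most one,
    earlier bins taking the remainder.  Q0 genes are sub-grouped Q0a/Q0b by
    2-means on their metaprofile rows when a matrix is supplied (Q0b is the
    lower-signal group).
    """
    samples = expr.sample_ids(condition=condition)
    if not samples:
        raise ValueError(f"no samples for condition {condition!r}")
    sub = fpkm[samples]
    mean_fpkm = sub.mean(axis=1)
    expressed = mean_fpkm.index[mean_fpkm > 0]
    if len(expressed) < 5:
        raise ValueError("need at least 5 expressed genes for quintiles")

    ranked = sorted(expressed, key=lambda g: (-mean_fpkm[g], g))
    n = len(ranked)
    base, rem = divmod(n, 5)
    sizes = [base + (1 if i < rem else 0) for i in range(5)]
    assignments: dict[str, str] = {}
    pos = 0
    for i, size in enumerate(sizes, start=1):
        for g in ranked[pos:pos + size]:
            assignments[g] = f"Q{i}"
        pos += size

    q0_genes = [g for g in mean_fpkm.index
                if (sub.loc[g] == 0).all()]
    for g in q0_genes:
        assignments[g] = "Q0"

    q0_sub: dict[str, str] = {}
    if matrix is not None and len(q0_genes) >= 2:
        present = [g for g in q0_genes if g in matrix.gene_ids]
        if len(present) >= 2:
            rows = matrix.rows(present)
            km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(rows)
            means = [rows[km.labels_ == j].mean() for j in (0, 1)]
            hi = int(np.argmax(means))
            for g, lab in zip(present, km.labels_):
                q0_sub[g] = "Q0a" if lab == hi else "Q0b"
    return QuintileAssignment(assignments, q0_sub)


def cluster_patterns(matrix: MetaprofileMatrix, k: int = 3, seed: int = 0,
                     n_restarts: int = 25) -> PatternClusters:
    """Euclidean k-means over metaprofile rows with semantic k1/k2/k3 labels.

    k-means++ init with ``n_restarts`` restarts, best inertia kept.  For
    k = 3, labels follow a centroid-shape rule: largest mean |value| in the
    gene-body core -> k1 (stress_related, broad gene body); of the rest, the
    larger TSS-zone peak minus body mean -> k2 (housekeeping, sharp TSS
    peak); the remaining centroid -> k3 (depleted).
    """
    X = matrix.values
    if X.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("degenerate matrix: fewer distinct rows than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed).fit(X)
    centroids = km.cluster_centers_

    if k == 3:
        body_mean_abs = np.abs(centroids[:, _BODY_CORE]).mean(axis=1)
        k1 = int(np.argmax(body_mean_abs))
        rest = [j for j in range(3) if j != k1]
        tss_sharpness = [
            centroids[j, _TSS_ZONE].max() - centroids[j, _BODY_CORE].mean()
            for j in rest
        ]
        k2 = rest[int(np.argmax(tss_sharpness))]
        k3 = next(j for j in rest if j != k2)
        name_of = {k1: "k1", k2: "k2", k3: "k3"}
        labels = {"k1": "stress_related", "k2": "housekeeping", "k3": "depleted"}
        order = [k1, k2, k3]
    else:
        name_of = {j: f"cluster_{j + 1}" for j in range(k)}
        labels = {}
        order = list(range(k))

    assignments = {g: name_of[int(lab)] for g, lab in zip(matrix.gene_ids, km.labels_)}
    return PatternClusters(assignments, centroids[order], labels)


def replicate_concordance(track_a: CoverageTrack, track_b: CoverageTrack,
                          bin: int = 1000) -> float:
    """Pearson r of genome-wide binned, library-scaled counts.

    Returns NaN when either re-binned track has zero variance.
    """
    if not track_a.same_grid(track_b):
        raise ValueError("tracks are not on the same window grid")
    W = track_a.window_size
    if bin % W != 0:
        raise ValueError("bin must be a multiple of the window size")
    factor = bin // W
    va, vb = [], []
    for chrom in sorted(track_a.counts):
        for track, acc in ((track_a, va), (track_b, vb)):
            vec = track.counts[chrom]
            n_full = (vec.size // factor) * factor
            acc.append(vec[:n_full].reshape(-1, factor).sum(axis=1))
    a = np.concatenate(va) / track_a.library_size
    b = np.concatenate(vb) / track_b.library_size
    if a.max() == a.min() or b.max() == b.min():
        return float("nan")
    return float(stats.pearsonr(a, b)[0])
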