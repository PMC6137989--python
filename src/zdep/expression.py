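"""RNA count normalization, FPKM, a simplified NB differential test and
fuzzy k-means interaction clustering.

The differential stage is a self-contained negative-binomial Wald test:
median-of-ratios size factors, method-of-moments dispersion shrunk
toward a fitted mean-dispersion trend, and a delta-method standard error on
the log2 fold change.  The regularized-log stand-in is a shifted log of
size-factor-normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues

__all__ = [
    "size_factors",
    "fpkm",
    "rlog_like",
    "de_test",
    "cluster_interactions",
    "InteractionClusters",
]

_DISP_FLOOR = 1e-8
_MEAN_EPS = 0.5  # pseudo-mean keeping fold changes and SEs finite at zero
# weight of the per-gene moment dispersion in the blend with the fitted
# trend; with two replicates the moment estimate is extremely noisy, and
# null simulations put the 0.3/0.7 blend at ~5% type-I with good power
_MOM_WEIGHT = 0.3


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Ratios are computed against per-gene geometric means over genes with
    strictly positive counts in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene with positive counts in every sample")
    logs = np.log(mat[all_pos])
    log_geo = logs.mean(axis=1, keepdims=True)
    log_sf = np.median(logs - log_geo, axis=0)
    log_sf -= log_sf.mean()  # geometric mean exactly 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene length for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    per_kb = counts.div(lengths / 1e3, axis=0)
    return per_kb.div(library_sizes / 1e6, axis=1)


def rlog_like(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Shifted log of normalized counts: log2(count / size_factor + 1)."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("invalid size factors")
    return np.log2(counts.div(factors, axis=1) + 1.0)


def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha = a0 + a1 / mu over usable genes."""
    ok = (mu > 0) & (alpha_mom > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 10:
        return 0.01, 1.0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
    return max(float(coef[0]), _DISP_FLOOR), max(float(coef[1]), 0.0)


def de_test(counts: pd.DataFrame, groups: dict[str, str],
            factors: pd.Series | None = None,
            alpha_fdr: float = 0.001) -> pd.DataFrame:
    """Per-gene NB Wald test of group B versus group A.

    ``groups`` maps each sample id to one of exactly two group labels; the
    log2 fold change is reported for the lexicographically later group
    relative to the earlier one.  Returns a DataFrame indexed by gene with
    columns base_mean, log2fc, se, p_value, q_value, direction.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    ga = [s for s in counts.columns if groups.get(s) == labels[0]]
    gb = [s for s in counts.columns if groups.get(s) == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need >= 2 replicates per group")
    if factors is None:
        factors = size_factors(counts[ga + gb])
    norm = counts[ga + gb].div(factors.reindex(ga + gb), axis=1).to_numpy(dtype=float)
    na, nb = len(ga), len(gb)
    A, B = norm[:, :na], norm[:, na:]

    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion pooled across the two groups
    var_within = (A.var(axis=1, ddof=1) + B.var(axis=1, ddof=1)) / 2
    mean_within = (mean_a + mean_b) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_within - mean_within) / mean_within**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)

    a0, a1 = _dispersion_trend(mean_within, alpha_mom)
    with np.errstate(divide="ignore"):
        alpha_trend = a0 + a1 / np.maximum(mean_within, _MEAN_EPS)
    alpha = np.maximum(
        _MOM_WEIGHT * np.maximum(alpha_mom, 0.0)
        + (1.0 - _MOM_WEIGHT) * alpha_trend,
        _DISP_FLOOR,
    )

    ma = mean_a + _MEAN_EPS
    mb = mean_b + _MEAN_EPS
    log2fc = np.log2(mb / ma)
    var_a = (ma + alpha * ma**2) / na
    var_b = (mb + alpha * mb**2) / nb
    se = np.sqrt(var_a / ma**2 + var_b / mb**2) / np.log(2)
    z = log2fc / se
    pvals = 2 * stats.norm.sf(np.abs(z))

    allzero = (mean_a == 0) & (mean_b == 0)
    pvals = np.where(allzero, 1.0, pvals)
    log2fc = np.where(allzero, 0.0, log2fc)

    qvals = bh_qvalues(pvals)
    direction = np.where(qvals < alpha_fdr,
                         np.where(log2fc > 0, "up", "down"), "ns")
    direction = np.where(allzero, "ns", direction)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p_value": pvals,
            "q_value": qvals,
            "direction": direction,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# Fuzzy k-means
# ---------------------------------------------------------------------------


@dataclass
class InteractionClusters:
    memberships: pd.DataFrame  # genes x clusters, rows sum to 1
    assignments: dict[str, str | None] = field(default_factory=dict)
    centroids: np.ndarray | None = None


def _fcm_once(X: np.ndarray, k: int, m: float, rng: np.random.Generator,
              max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    u = np.full((n, k), 1.0 / k)
    prev_obj = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        expo = -1.0 / (m - 1.0)
        # normalize by the per-row minimum before powering so the weights
        # stay in (0, 1] and cannot overflow for fuzziness close to 1
        w = (d2 / d2.min(axis=1, keepdims=True)) ** expo
        u = w / w.sum(axis=1, keepdims=True)
        um = u**m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        obj = float((um * d2).sum())
        if abs(prev_obj - obj) < tol * max(abs(prev_obj), 1.0):
            break
        prev_obj = obj
    return u, centroids, obj


def cluster_interactions(rlog_matrix: pd.DataFrame, k: int,
                         fuzziness: float = 1.2, cutoff: float = 0.5,
                         seed: int = 0, n_restarts: int = 5,
                         max_iter: int = 300, tol: float = 1e-9) -> InteractionClusters:
    """Fuzzy c-means over row-standardized expression profiles.

    Genes are assigned to their argmax cluster iff its membership is at
    least ``cutoff``; clusters are ordered by assigned size (descending)
    and named C1..Ck.
    """
    if k > rlog_matrix.shape[0]:
        raise ValueError("k exceeds number of genes")
    if fuzziness <= 1:
        raise ValueError("fuzziness must be > 1")
    X = rlog_matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    X = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)

    best = None
    master = np.random.default_rng(seed)
    for _ in range(n_restarts):
        u, centroids, obj = _fcm_once(X, k, fuzziness, master, max_iter, tol)
        if best is None or obj < best[2]:
            best = (u, centroids, obj)
    u, centroids, _ = best

    argmax = u.argmax(axis=1)
    maxmem = u.max(axis=1)
    sizes = [(int(((argmax == j) & (maxmem >= cutoff)).sum()), j) for j in range(k)]
    order = [j for _, j in sorted(sizes, key=lambda t: (-t[0], t[1]))]
    names = {j: f"C{rank + 1}" for rank, j in enumerate(order)}

    memberships = pd.DataFrame(
        u[:, order], index=rlog_matrix.index, columns=[f"C{r + 1}" for r in range(k)]
    )
    assignments = {
        g: (names[int(j)] if mm >= cutoff else None)
        for g, j, mm in zip(rlog_matrix.index, argmax, maxmem)
    }
    return InteractionClusters(memberships, assignments, centroids[order])
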