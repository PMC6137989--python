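"""Bootstrap overlap-enrichment of DEG sets among differential-H2A.Z gene
categories, and hypergeometric term enrichment (SEA-style).

The bootstrap draws ``|deg_set|`` genes from the background without
replacement per iteration and records the overlap with the category; the
resampled mean +/- SD describes the null.  Significance of the observed
overlap is an exact binomial test with success probability K/N, one-sided
in the direction of the deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues
from .regions import CATEGORIES, GeneDifferentialCall

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "bootstrap_overlap",
    "sea_enrichment",
    "overlap_summary",
]


@dataclass(frozen=True)
class BootstrapResult:
    deg_set_size: int          # m
    category_size: int         # K
    background_size: int       # N
    observed_overlap: int      # x
    null_mean: float
    null_sd: float
    n_iterations: int
    binomial_p: float
    direction: str             # over / under
    degenerate: bool = False


def bootstrap_overlap(deg_set, category_set, background, n_iter: int = 1000,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> BootstrapResult:
    """Observed DEG/category overlap versus a resampled null.

    ``deg_set`` and ``category_set`` must be subsets of ``background``.
    Each iteration samples ``|deg_set|`` background genes without
    replacement; the binomial test uses m = |deg_set| trials at
    p0 = K/N, one-sided toward the observed deviation.
    """
    deg = set(deg_set)
    cat = set(category_set)
    bg = sorted(set(background))
    if not deg or not cat:
        raise ValueError("deg_set and category_set must be non-empty")
    if not deg <= set(bg) or not cat <= set(bg):
        raise ValueError("deg_set and category_set must be subsets of background")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    m, K, N = len(deg), len(cat), len(bg)
    x = len(deg & cat)

    if rng is None:
        rng = np.random.default_rng(seed)
    in_cat = np.fromiter((g in cat for g in bg), dtype=bool, count=N)
    overlaps = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        idx = rng.choice(N, size=m, replace=False)
        overlaps[i] = int(in_cat[idx].sum())
    null_mean = float(overlaps.mean())
    null_sd = float(overlaps.std(ddof=0))

    p0 = K / N
    expected = m * p0
    if x > expected:
        direction = "over"
        p = float(stats.binom.sf(x - 1, m, p0))
    else:
        direction = "under"
        p = float(stats.binom.cdf(x, m, p0))
    degenerate = null_sd == 0.0 or p0 in (0.0, 1.0)
    if degenerate:
        logger.warning("bootstrap overlap test is degenerate (K=%d of N=%d)", K, N)
    return BootstrapResult(m, K, N, x, null_mean, null_sd, n_iter, p,
                           direction, degenerate)


def sea_enrichment(query_genes, term_annotation: dict[str, set[str]],
                   background, alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term, BH-corrected.

    Terms with no background members are skipped with a warning.  Returns a
    DataFrame (term_id, k, n, K, N, p_value, q_value, significant) sorted
    by p-value; significance is q < ``alpha``.
    """
    query = set(query_genes)
    bg = set(background)
    if not query <= bg:
        raise ValueError("query must be a subset of background")
    N, n = len(bg), len(query)
    rows = []
    for term_id in sorted(term_annotation):
        members = set(term_annotation[term_id]) & bg
        K = len(members)
        if K == 0:
            logger.warning("term %s absent from background; skipped", term_id)
            continue
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "k": k, "n": n, "K": K, "N": N,
                     "p_value": p})
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_value"])
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] < alpha
    return df.sort_values(["p_value", "term_id"]).reset_index(drop=True)


def overlap_summary(de_results: pd.DataFrame,
                    gene_calls: list[GeneDifferentialCall],
                    background, n_iter: int = 1000,
                    seed: int | None = None) -> dict[tuple[str, str], BootstrapResult]:
    """Bootstrap overlap for every (DEG direction) x (differential category).

    ``de_results`` is the output of :func:`zdep.expression.de_test`;
    ``background`` should be the analysis universe (by default expressed
    protein-coding genes).  Cells whose DEG or category set is empty are
    omitted.
    """
    bg = set(background)
    deg_sets = {
        d: set(de_results.index[de_results["direction"] == d]) & bg
        for d in ("up", "down")
    }
    cat_sets = {
        c: {call.gene_id for call in gene_calls if c in call.categories} & bg
        for c in CATEGORIES
    }
    # one child seed per category, reused across directions: the null draw
    # stream then depends only on (deg set, category), so relabelling the
    # DEG directions swaps matrix rows exactly
    child_seeds = dict(zip(CATEGORIES, np.random.SeedSequence(seed).spawn(len(CATEGORIES))))
    out: dict[tuple[str, str], BootstrapResult] = {}
    for d in ("up", "down"):
        for c in CATEGORIES:
            if not deg_sets[d] or not cat_sets[c]:
                continue
            out[(d, c)] = bootstrap_overlap(
                deg_sets[d], cat_sets[c], bg, n_iter=n_iter,
                rng=np.random.default_rng(child_seeds[c]))
    return out
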