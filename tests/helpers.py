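"""Independent brute-force oracles used by the test suite.

Everything here is written as a direct, loop-based transliteration of the
documented algorithms, kept deliberately separate from the package
implementation so the two can disagree.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats


def brute_bh(pvalues, n_tests=None):
    """Literal BH step-up: q_i = min over j with p_(j) >= p_i of m p_(j)/j."""
    p = list(map(float, pvalues))
    m = len(p)
    n_tests = m if n_tests is None else n_tests
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n_tests / rank)
        q[i] = running
    return np.array(q)


def exact_binom_upper(x, n, p):
    """P(X >= x) for Binomial(n, p) via exact rational summation."""
    pf = Fraction(p).limit_denominator(10**12)
    total = Fraction(0)
    for i in range(x, n + 1):
        total += comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


def exact_binom_lower(x, n, p):
    pf = Fraction(p).limit_denominator(10**12)
    total = Fraction(0)
    for i in range(0, x + 1):
        total += comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


def exact_binom_twosided(k, n, p):
    """Two-sided exact binomial test by the minlike method."""
    pf = Fraction(p).limit_denominator(10**12)
    probs = [comb(n, i) * pf**i * (1 - pf) ** (n - i) for i in range(n + 1)]
    pk = probs[k]
    # tolerate tiny float representation slack like scipy does
    total = sum(pr for pr in probs if pr <= pk * Fraction(1 + 10**-7))
    return float(min(Fraction(1), total))


def exact_hypergeom_upper(k, N, K, n):
    """P(X >= k) for Hypergeometric(N, K, n) via exact rational summation."""
    denom = comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return float(Fraction(total, denom))


def brute_islands(chip_counts, control_counts, params):
    """Brute-force reimplementation of the island caller.

    Enumerates eligible windows one by one, grows islands by explicit gap
    scanning, and recomputes every probability from first principles.
    Returns a list of dicts with chrom/start/end/p/q (pre-FDR-filter
    candidates carry q as well; the caller filters).
    """
    chip_lib = float(sum(np.sum(v) for v in chip_counts.values()))
    ctrl_lib = float(sum(np.sum(v) for v in control_counts.values()))
    n_windows = int(sum(len(v) for v in chip_counts.values()))
    if chip_lib <= 0:
        raise ValueError("zero chip depth")
    scale = chip_lib / ctrl_lib if ctrl_lib > 0 else 0.0
    p0 = chip_lib / (chip_lib + ctrl_lib) if ctrl_lib > 0 else 1.0
    floor = chip_lib / n_windows * params.effective_genome_fraction
    gap_w = params.gap // params.window

    candidates = []
    for chrom in sorted(chip_counts):
        c = chip_counts[chrom]
        t = control_counts[chrom]
        eligible = []
        for w in range(len(c)):
            lam = max(t[w] * scale, floor)
            pv = stats.poisson.sf(round(c[w]) - 1, lam)
            if pv < params.window_pvalue_cutoff:
                eligible.append(w)
        # group eligible windows: bridge runs of ineligible windows <= gap_w
        groups = []
        for w in eligible:
            if groups and w - groups[-1][-1] - 1 <= gap_w:
                groups[-1].append(w)
            else:
                groups.append([w])
        for grp in groups:
            lo, hi = grp[0], grp[-1]
            chip_tot = int(round(sum(c[lo:hi + 1])))
            ctrl_tot = int(round(sum(t[lo:hi + 1])))
            p = exact_binom_upper(chip_tot, chip_tot + ctrl_tot, p0)
            candidates.append({
                "chrom": chrom,
                "start": lo * params.window,
                "end": (hi + 1) * params.window,
                "p": p,
            })
    qs = brute_bh([cand["p"] for cand in candidates], n_tests=n_windows) \
        if candidates else []
    out = []
    for cand, q in zip(candidates, qs):
        if q < params.island_fdr:
            cand["q"] = float(q)
            out.append(cand)
    out.sort(key=lambda d: (d["chrom"], d["start"]))
    return out
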