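"""Small shared statistics helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["bh_qvalues"]


def bh_qvalues(pvalues, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Standard step-up with a cumulative minimum over the sorted p-values,
    so the result is monotone in p and always satisfies ``q >= p``.
    ``n_tests`` overrides the number of tests when the supplied p-values
    are a data-selected subset of a larger candidate family (equivalent to
    padding with p = 1 entries).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    n = p.size
    if n == 0:
        return np.empty(0, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    if n_tests is None:
        n_tests = n
    elif n_tests < n:
        raise ValueError("n_tests must be >= len(pvalues)")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n_tests / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    # q >= p holds mathematically; guard against one-ulp rounding in p*n/rank
    return np.maximum(q, p)
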