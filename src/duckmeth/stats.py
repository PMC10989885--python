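"""Shared statistical primitives: binomial tails and BH step-up FDR."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["binomial_tail", "bh_correct"]


def binomial_tail(successes, trials, p0) -> np.ndarray:
    """One-sided upper-tail binomial probability P(X >= successes).

    Degenerate backgrounds: p0 == 0 gives p = 1 when successes == 0 and
    p = 0 otherwise; p0 == 1 gives p = 1.
    """
    k = np.asarray(successes, dtype=np.int64)
    n = np.asarray(trials, dtype=np.int64)
    if np.any(k > n):
        raise ValueError("successes exceed trials")
    if np.any(k < 0) or np.any(n < 0):
        raise ValueError("negative counts")
    p0 = float(p0)
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("background probability outside [0, 1]")
    if p0 == 0.0:
        return np.where(k == 0, 1.0, 0.0) if k.ndim else (1.0 if k == 0 else 0.0)
    if p0 == 1.0:
        return np.ones_like(k, dtype=float) if k.ndim else 1.0
    # P(X >= k) = sf(k - 1)
    return stats.binom.sf(k - 1, n, p0)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min over j >= i of min(1, m * p_(j) / j) in sorted order, mapped
    back to the input order; ties handled stably.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q
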