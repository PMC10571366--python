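"""Shared statistical primitives (vectorized Fisher exact, BH step-up)."""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

# relative tolerance when collecting outcomes "as or more extreme" in the
# two-sided Fisher sum; matches the convention of R/scipy
_FISHER_REL_EPS = 1e-7


def _log_hypergeom_pmf(k: np.ndarray, n: int, K: int, N: int) -> np.ndarray:
    """log P(X=k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table.
    """
    N = a + b + c + d
    if N == 0:
        return 1.0
    K = a + b      # row 1 total
    n = a + c      # column 1 total
    lo = max(0, n - (N - K))
    hi = min(K, n)
    ks = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(ks, n, K, N)
    p_obs = logp[a - lo]
    mask = logp <= p_obs + np.log1p(_FISHER_REL_EPS)
    return float(min(1.0, np.exp(logp[mask]).sum()))


def fisher_exact_many(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p for many 2x2 tables.

    Parameters
    ----------
    tables : int array of shape (n, 4)
        Rows are (a, b, c, d) for tables [[a, b], [c, d]].
    """
    tables = np.asarray(tables, dtype=np.int64)
    out = np.ones(len(tables))
    for i, (a, b, c, d) in enumerate(tables):
        out[i] = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
    return out


def bh_stepup(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
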