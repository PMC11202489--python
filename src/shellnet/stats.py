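"""Shared statistical kernels: hypergeometric over-representation test,
Benjamini-Hochberg adjustment, and the midrank Spearman coefficient.

Both the ceRNA shared-miRNA test and the term-enrichment test call the single
:func:`hypergeom_sf_shared` kernel, so one oracle suite covers both.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def hypergeom_sf_shared(m: int, n: int, K: int, N: int) -> float:
    """P(X >= m) with X ~ Hypergeometric(N, K, n).

    Drawing ``n`` items from a universe of ``N`` of which ``K`` are marked,
    the probability of seeing at least ``m`` marked items. This is the
    one-sided over-representation p-value used for both the shared-miRNA
    screen (m = shared miRNAs, n = circRNA's miRNAs, K = mRNA's miRNAs,
    N = miRNA universe) and term enrichment (m = hits, n = gene-set size,
    K = term size, N = gene universe).
    """
    if min(m, n, K, N) < 0 or m > min(n, K) or n > N or K > N:
        raise ValueError(f"inconsistent counts: m={m}, n={n}, K={K}, N={N}")
    if m == 0:
        return 1.0
    # survival function at m-1 gives P(X >= m)
    return float(sps.hypergeom.sf(m - 1, N, K, n))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    adjusted_i = min_{j >= i} p_(j) * m / j (in sorted order), clipped at 1,
    returned in the input order. Raises on p-values outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    scaled = p[order] * m / ranks
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj_sorted
    return out


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Ties receive average ranks. A constant vector has no rank ordering, so
    its correlation with anything is defined as 0.0 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rx = _midranks(x)
    ry = _midranks(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx * sx).sum() * (sy * sy).sum())
    if denom == 0.0:  # at least one constant vector
        return 0.0
    return float((sx * sy).sum() / denom)


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Spearman between rows of ``a`` and rows of ``b``.

    Vectorised midrank + Pearson over a shared sample axis; rows that are
    constant yield 0.0 against everything (matching :func:`spearman`).
    Returns an (a_rows, b_rows) matrix.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("row length mismatch")
    ra = np.apply_along_axis(_midranks, 1, a)
    rb = np.apply_along_axis(_midranks, 1, b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra * ra).sum(axis=1))
    nb = np.sqrt((rb * rb).sum(axis=1))
    num = ra @ rb.T
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), 0.0)
    return rho
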