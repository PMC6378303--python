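"""Mantel and partial Mantel permutation tests between distance matrices.

The Mantel statistic is the Pearson correlation over the n(n-1)/2
off-diagonal pairs; significance comes from simultaneously permuting the
rows and columns of the first matrix. The partial statistic is the usual
first-order partial correlation r12.3 recomputed for every permutation of
the first matrix. Tests are one-sided for positive association by
default.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix


def _condensed(dm) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(dm.data if isinstance(dm, DistanceMatrix) else dm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return d, np.asarray(iu)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def mantel(d1, d2, n_perm: int = 999, seed=None,
           alternative: str = "greater") -> tuple[float, float]:
    """Mantel test between two conformable distance matrices.

    Returns ``(r, p)`` with ``p = (1 + #{r_null >= r}) / (1 + n_perm)``
    for the default one-sided (positive association) alternative.
    """
    m1, iu = _condensed(d1)
    m2, _ = _condensed(d2)
    if m1.shape != m2.shape:
        raise ValueError("matrices must have the same shape")
    n = m1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for a Mantel test")
    v1 = m1[iu[0], iu[1]]
    v2 = m2[iu[0], iu[1]]
    r = _pearson(v1, v2)
    if n_perm <= 0:
        return r, np.nan
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = m1[np.ix_(perm, perm)][iu[0], iu[1]]
        rp = _pearson(vp, v2)
        if alternative == "greater":
            exceed += rp >= r
        elif alternative == "less":
            exceed += rp <= r
        else:
            exceed += abs(rp) >= abs(r)
    return r, (1.0 + exceed) / (1.0 + n_perm)


def _partial_r(v1, v2, v3) -> float:
    r12 = _pearson(v1, v2)
    r13 = _pearson(v1, v3)
    r23 = _pearson(v2, v3)
    if abs(r13) >= 1.0 - 1e-12 or abs(r23) >= 1.0 - 1e-12:
        # controlling for (a copy of) the tested matrix itself removes the
        # whole association: the 0/0 limit is 0
        if abs(r12 - r13 * r23) < 1e-12:
            return 0.0
        raise ValueError("control matrix perfectly correlated with an input")
    return (r12 - r13 * r23) / np.sqrt((1 - r13 ** 2) * (1 - r23 ** 2))


def partial_mantel(d1, d2, d3, n_perm: int = 999, seed=None,
                   alternative: str = "greater") -> tuple[float, float]:
    """Partial Mantel test of d1 ~ d2 controlling for d3."""
    m1, iu = _condensed(d1)
    m2, _ = _condensed(d2)
    m3, _ = _condensed(d3)
    if not (m1.shape == m2.shape == m3.shape):
        raise ValueError("matrices must have the same shape")
    n = m1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for a Mantel test")
    v1 = m1[iu[0], iu[1]]
    v2 = m2[iu[0], iu[1]]
    v3 = m3[iu[0], iu[1]]
    r = _partial_r(v1, v2, v3)
    if n_perm <= 0:
        return float(r), np.nan
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = m1[np.ix_(perm, perm)][iu[0], iu[1]]
        rp = _partial_r(vp, v2, v3)
        if alternative == "greater":
            exceed += rp >= r
        elif alternative == "less":
            exceed += rp <= r
        else:
            exceed += abs(rp) >= abs(r)
    return float(r), (1.0 + exceed) / (1.0 + n_perm)
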