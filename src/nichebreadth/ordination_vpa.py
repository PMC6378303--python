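"""Constrained ordination (RDA, CCA) and variation partitioning (VPA).

RDA regresses a (by default Hellinger-transformed, column-centred)
community matrix on standardised explanatory variables and
eigen-decomposes the fitted values; R2 is the fitted share of the total
sum of squares. CCA does the analogous weighted analysis on the
correspondence-analysis (chi-square) residuals, whose total inertia equals
the contingency chi-square statistic over the grand total.

Variation partitioning splits community variance into pure environmental
(E|S), pure spatial (S|E), shared and unexplained fractions via Ezekiel-
adjusted R2 of the env-only, space-only and joint models. Adjusted R2 may
be negative; fractions are reported unfloored so they always sum to one.
Pure fractions are tested by permuting residuals of the reduced model
(partial RDA); the shared fraction is not testable and gets no p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Hellinger transform of a samples x taxa count matrix: sqrt of row-
    normalised relative abundances."""
    x = np.asarray(counts, dtype=float)
    rows = x.sum(axis=1, keepdims=True)
    if np.any(rows <= 0):
        raise ValueError("empty rows in community matrix")
    return np.sqrt(x / rows)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment 1 - (1 - r2)(n - 1)/(n - p - 1); may be negative."""
    if n - p - 1 < 1:
        raise ValueError(f"adjusted R2 undefined for n={n}, p={p}")
    if p == 0:
        return float(r2)
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


@dataclass
class ConstrainedOrdinationResult:
    eigenvalues: np.ndarray               # constrained axes, non-increasing
    unconstrained_eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    total_inertia: float
    constrained_inertia: float
    r2: float
    adj_r2: float
    p: float | None = None
    dropped_columns: list[str] | None = None

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia


def _clean_X(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i + 1}" for i in range(x.shape[1])]
    return x, names, []


def _drop_collinear(xc: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """QR-prune columns that are (numerically) linear combinations of
    earlier ones; returns kept matrix, kept names, dropped names."""
    kept_idx: list[int] = []
    dropped: list[str] = []
    basis = np.empty((xc.shape[0], 0))
    for j in range(xc.shape[1]):
        v = xc[:, j:j + 1]
        r = v - basis @ (basis.T @ v)
        if np.linalg.norm(r) > 1e-9 * max(1.0, np.linalg.norm(v)):
            basis = np.column_stack([basis, r / np.linalg.norm(r)])
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    return xc[:, kept_idx], [names[i] for i in kept_idx], dropped


def rda(Y, X, n_perm: int = 0, seed=None) -> ConstrainedOrdinationResult:
    """Redundancy analysis of response Y (samples x taxa, already
    transformed/centred as desired) on explanatory X.

    Y is column-centred internally; X is standardised. Collinear X columns
    are dropped with a warning. With ``n_perm`` > 0, an overall
    permutation test of the constrained variance is run.
    """
    y = np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    x, names, _ = _clean_X(X)
    if x.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    if n <= x.shape[1]:
        raise ValueError("need more samples than explanatory columns")
    yc = y - y.mean(axis=0, keepdims=True)
    xc = x - x.mean(axis=0, keepdims=True)
    sd = xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xc = xc / sd
    xc, names, dropped = _drop_collinear(xc, names)
    if dropped:
        import warnings
        warnings.warn(f"dropping collinear explanatory columns: {dropped}")
    q, _ = np.linalg.qr(xc)
    fitted = q @ (q.T @ yc)
    tot_ss = float(np.sum(yc ** 2))
    fit_ss = float(np.sum(fitted ** 2))
    r2 = fit_ss / tot_ss if tot_ss > 0 else 0.0

    # eigen-analysis of fitted values; inertia scaled by n-1 as variance
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = (s ** 2) / (n - 1)
    keep = eig > max(eig[0], 1e-300) * 1e-12 if eig.size else np.array([], bool)
    eig, u, s, vt = eig[keep], u[:, keep], s[keep], vt[keep]
    resid = yc - fitted
    s_res = np.linalg.svd(resid, compute_uv=False)
    eig_res = (s_res ** 2) / (n - 1)
    eig_res = eig_res[eig_res > max(eig_res[0], 1e-300) * 1e-12] if eig_res.size else eig_res

    site = pd.DataFrame(u * s, columns=[f"RDA{i+1}" for i in range(eig.size)])
    # variable scores: correlations of X with constrained site axes
    if eig.size and xc.shape[1]:
        with np.errstate(invalid="ignore"):
            vs = np.corrcoef(xc.T, site.to_numpy().T)[:xc.shape[1], xc.shape[1]:]
        vs = np.nan_to_num(vs)
    else:
        vs = np.zeros((xc.shape[1], eig.size))
    var_scores = pd.DataFrame(vs, index=names, columns=site.columns)

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            exceed += float(np.sum((q @ (q.T @ yp)) ** 2)) >= fit_ss
        p = (1.0 + exceed) / (1.0 + n_perm)

    adj = adjusted_r2(r2, n, xc.shape[1])
    return ConstrainedOrdinationResult(
        eigenvalues=eig, unconstrained_eigenvalues=eig_res,
        site_scores=site, variable_scores=var_scores,
        total_inertia=tot_ss / (n - 1), constrained_inertia=fit_ss / (n - 1),
        r2=r2, adj_r2=adj, p=p, dropped_columns=dropped)


def cca(Y, X, n_perm: int = 0, seed=None) -> ConstrainedOrdinationResult:
    """Canonical correspondence analysis of non-negative Y on X.

    Total inertia is the chi-square statistic of Y (as a contingency
    table) divided by its grand total.
    """
    y = np.asarray(Y, dtype=float)
    if np.any(y < 0):
        raise ValueError("CCA requires non-negative response values")
    if np.any(y.sum(axis=1) <= 0) or np.any(y.sum(axis=0) <= 0):
        raise ValueError("CCA requires positive row and column sums")
    n = y.shape[0]
    grand = y.sum()
    p_mat = y / grand
    r = p_mat.sum(axis=1)
    c = p_mat.sum(axis=0)
    expected = np.outer(r, c)
    qbar = (p_mat - expected) / np.sqrt(expected)    # chi-square residuals

    x, names, _ = _clean_X(X)
    if x.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    # row-mass weighted centring and standardisation of X
    xw = x - (r[:, None] * x).sum(axis=0)
    sd = np.sqrt((r[:, None] * xw ** 2).sum(axis=0))
    sd[sd == 0] = 1.0
    xw = xw / sd
    xw, names, dropped = _drop_collinear(np.sqrt(r)[:, None] * xw, names)
    if dropped:
        import warnings
        warnings.warn(f"dropping collinear explanatory columns: {dropped}")
    q, _ = np.linalg.qr(xw)
    fitted = q @ (q.T @ qbar)
    tot = float(np.sum(qbar ** 2))
    fit = float(np.sum(fitted ** 2))
    r2 = fit / tot if tot > 0 else 0.0

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2
    keep = eig > max(eig[0], 1e-300) * 1e-12 if eig.size else np.array([], bool)
    eig, u, s = eig[keep], u[:, keep], s[keep]
    resid = qbar - fitted
    s_res = np.linalg.svd(resid, compute_uv=False)
    eig_res = (s_res ** 2)
    eig_res = eig_res[eig_res > 1e-12 * max(1.0, eig_res.max())] if eig_res.size else eig_res

    with np.errstate(divide="ignore", invalid="ignore"):
        site_raw = u * s / np.sqrt(r)[:, None]       # weighted site scores
    site = pd.DataFrame(site_raw, columns=[f"CCA{i+1}" for i in range(eig.size)])
    var_scores = pd.DataFrame(
        q.T @ (u * s) if eig.size else np.zeros((q.shape[1], 0)),
        index=names[:q.shape[1]], columns=site.columns)

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            exceed += float(np.sum((q @ (q.T @ qbar[perm])) ** 2)) >= fit
        p = (1.0 + exceed) / (1.0 + n_perm)

    adj = adjusted_r2(r2, n, xw.shape[1])
    return ConstrainedOrdinationResult(
        eigenvalues=eig, unconstrained_eigenvalues=eig_res,
        site_scores=site, variable_scores=var_scores,
        total_inertia=tot, constrained_inertia=fit,
        r2=r2, adj_r2=adj, p=p, dropped_columns=dropped)


@dataclass
class VariancePartition:
    pure_env: float
    pure_spatial: float
    shared: float
    unexplained: float
    p_pure_env: float | None
    p_pure_spatial: float | None
    n: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("pure_env (E|S)", self.pure_env, self.p_pure_env),
            ("pure_spatial (S|E)", self.pure_spatial, self.p_pure_spatial),
            ("shared", self.shared, None),
            ("unexplained", self.unexplained, None),
        ]
        return pd.DataFrame(rows, columns=["fraction", "adj_r2", "p"])


def _partial_test(yc: np.ndarray, x_test: np.ndarray, x_cond: np.ndarray,
                  n_perm: int, rng) -> float:
    """Permutation p for the added variance of x_test given x_cond, permuting
    residuals of the reduced (conditioning) model."""
    n = yc.shape[0]
    qc, _ = np.linalg.qr(x_cond) if x_cond.shape[1] else (np.empty((n, 0)), None)
    fitted_c = qc @ (qc.T @ yc) if x_cond.shape[1] else np.zeros_like(yc)
    resid_c = yc - fitted_c
    both = np.column_stack([x_cond, x_test])
    qb, _ = np.linalg.qr(both)
    obs = float(np.sum((qb @ (qb.T @ yc)) ** 2) - np.sum(fitted_c ** 2))
    exceed = 0
    for _ in range(n_perm):
        yp = fitted_c + resid_c[rng.permutation(n)]
        add = float(np.sum((qb @ (qb.T @ yp)) ** 2)
                    - np.sum((qc @ (qc.T @ yp)) ** 2 if x_cond.shape[1] else 0.0))
        exceed += add >= obs
    return (1.0 + exceed) / (1.0 + n_perm)


def variation_partition(Y, X_env, X_spatial, n_perm: int = 999,
                        seed=None) -> VariancePartition:
    """Two-set variation partitioning by (partial) RDA with adjusted R2.

    ``Y`` should already carry the desired transform (Hellinger by
    default upstream); both explanatory sets are expected to be
    forward-selected beforehand. Either set may be empty (``None`` or zero
    columns), reducing to a single-set decomposition.
    """

    def _mat(X):
        if X is None:
            return np.empty((np.asarray(Y).shape[0], 0)), []
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        a = np.asarray(X, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        return a, [f"x{i+1}" for i in range(a.shape[1])]

    y = np.asarray(Y, dtype=float)
    n = y.shape[0]
    xe, _ = _mat(X_env)
    xs, _ = _mat(X_spatial)
    if xe.shape[1] == 0 and xs.shape[1] == 0:
        raise ValueError("both explanatory sets are empty")
    yc = y - y.mean(axis=0, keepdims=True)
    tot = float(np.sum(yc ** 2))

    def _std(x):
        if x.shape[1] == 0:
            return x
        xc = x - x.mean(axis=0, keepdims=True)
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
        xc, _, _ = _drop_collinear(xc, [str(i) for i in range(xc.shape[1])])
        return xc

    xe, xs = _std(xe), _std(xs)

    def _adj(x):
        if x.shape[1] == 0:
            return 0.0
        q, _ = np.linalg.qr(x)
        return adjusted_r2(float(np.sum((q @ (q.T @ yc)) ** 2)) / tot, n, x.shape[1])

    joint = _drop_collinear(np.column_stack([xe, xs]),
                            [str(i) for i in range(xe.shape[1] + xs.shape[1])])[0]
    ab = _adj(xe)       # a + b
    bc = _adj(xs)       # b + c
    abc = _adj(joint)
    a = abc - bc
    c_frac = abc - ab
    b = ab + bc - abc
    d = 1.0 - abc

    rng = np.random.default_rng(seed)
    p_a = p_c = None
    if n_perm > 0 and xe.shape[1] and xs.shape[1]:
        p_a = _partial_test(yc, xe, xs, n_perm, rng)
        p_c = _partial_test(yc, xs, xe, n_perm, rng)
    elif n_perm > 0:
        if xe.shape[1]:
            p_a = _partial_test(yc, xe, np.empty((n, 0)), n_perm, rng)
        if xs.shape[1]:
            p_c = _partial_test(yc, xs, np.empty((n, 0)), n_perm, rng)
    return VariancePartition(pure_env=a, pure_spatial=c_frac, shared=b,
                             unexplained=d, p_pure_env=p_a, p_pure_spatial=p_c,
                             n=n)
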