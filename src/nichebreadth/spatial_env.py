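"""Spatial eigenvector analysis and permutation-based forward selection.

PCNM (principal coordinates of neighbour matrices) turns a geographic
distance matrix into orthogonal spatial eigenvectors usable as explanatory
variables in constrained ordination: distances beyond a truncation
threshold (default: the longest edge of the minimum spanning tree, which
keeps the site graph connected) are replaced by four times the threshold,
and the PCoA eigenvectors of the modified matrix with positive eigenvalues
are retained.

Forward selection adds explanatory variables greedily by added constrained
variance, with double stopping. Each step's permutation statistic is the
maximum added R2 over the remaining candidates, so the entry test is
calibrated: under pure noise the probability of selecting anything at all
is ~alpha, not inflated by the number of candidates (and, unlike a global
test of the full candidate model, the statistic keeps its power when the
candidate set nearly saturates the sample size). Selection additionally
stops once the adjusted R2 of the selected set would exceed that of the
full candidate model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community_io import SampleMetadata
from .ordination_vpa import adjusted_r2


def geo_distance(metadata: SampleMetadata) -> DistanceMatrix:
    """Euclidean distances on the planar (x_m, y_m) coordinates."""
    coords = metadata.coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return DistanceMatrix(squareform(pdist(coords)), ids=list(metadata.sample_ids))


@dataclass
class SpatialEigenvectors:
    """Retained positive-eigenvalue PCNM axes (unit-norm eigenvectors)."""

    scores: pd.DataFrame      # samples x PCNM1..PCNMk
    eigenvalues: np.ndarray
    truncation: float


def pcnm(dm_geo: DistanceMatrix, truncation: float | None = None
         ) -> SpatialEigenvectors:
    """Spatial eigenvectors of a truncated geographic distance matrix."""
    d = np.asarray(dm_geo.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites for PCNM")
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    if truncation <= 0:
        raise ValueError("truncation distance must be positive")
    dt = d.copy()
    dt[dt > truncation] = 4.0 * truncation
    np.fill_diagonal(dt, 0.0)
    # Gower centring of -0.5 * D^2
    a = -0.5 * dt ** 2
    a -= a.mean(axis=0, keepdims=True)
    a -= a.mean(axis=1, keepdims=True)
    a += a.mean()
    eigval, eigvec = np.linalg.eigh((a + a.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-10
    keep = eigval > tol
    scores = pd.DataFrame(eigvec[:, keep],
                          index=pd.Index(dm_geo.ids, name="sample_id"),
                          columns=[f"PCNM{i + 1}" for i in range(int(keep.sum()))])
    return SpatialEigenvectors(scores, eigval[keep], truncation)


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    steps: pd.DataFrame       # variable, added_r2, cum_adj_r2, p
    full_model_adj_r2: float


def _fitted_ss(yc: np.ndarray, basis: np.ndarray) -> float:
    """Sum of squares of the projection of column-centred yc onto the
    orthonormal basis (n x k)."""
    if basis.shape[1] == 0:
        return 0.0
    proj = basis.T @ yc
    return float(np.sum(proj ** 2))


def _orthonormal(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the centred column space of x."""
    if x.shape[1] == 0:
        return x
    xc = x - x.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def forward_select(Y, candidates: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 999, seed=None) -> ForwardSelectionResult:
    """Greedy forward selection of explanatory variables for a multivariate
    response (rows = samples).

    ``Y`` is used as given (transform upstream, e.g. Hellinger). Ties in
    added variance break lexicographically by variable name.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if candidates.shape[0] != n:
        raise ValueError("candidates and response must have matching rows")
    # drop duplicate columns (same values), keeping first by name order
    cand = candidates.loc[:, ~candidates.T.duplicated()]
    names = sorted(cand.columns)
    yc = y - y.mean(axis=0, keepdims=True)
    tot_ss = float(np.sum(yc ** 2))
    if tot_ss == 0:
        raise ValueError("constant response matrix")

    full_basis = _orthonormal(cand[names].to_numpy(dtype=float))
    full_r2 = _fitted_ss(yc, full_basis) / tot_ss
    full_adj = adjusted_r2(full_r2, n, full_basis.shape[1])

    selected: list[str] = []
    rows = []
    resid = yc.copy()
    basis = np.empty((n, 0))
    while names:
        # residualised unit direction and added R2 for each candidate
        added, xres = {}, {}
        for nm in names:
            x = cand[nm].to_numpy(dtype=float)[:, None]
            xc = x - x.mean()
            xr = xc - basis @ (basis.T @ xc)
            nrm = np.linalg.norm(xr)
            if nrm < 1e-10:
                added[nm] = -np.inf      # collinear with selected set
                continue
            xres[nm] = xr[:, 0] / nrm
            added[nm] = float(np.sum((xres[nm] @ resid) ** 2)) / tot_ss
        best = max(sorted(added), key=lambda nm: added[nm])
        if not np.isfinite(added[best]):
            break
        # permutation test of the max added R2 over candidates (residuals of
        # the current model are exchangeable under H0)
        xr_mat = np.array([xres[nm] for nm in sorted(xres)])   # k x n
        obs = added[best] * tot_ss
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            exceed += np.max(np.sum((xr_mat @ resid[perm]) ** 2, axis=1)) >= obs
        p = (1.0 + exceed) / (1.0 + n_perm)
        if p >= alpha:
            break
        trial_basis = _orthonormal(
            cand[selected + [best]].to_numpy(dtype=float))
        trial_adj = adjusted_r2(_fitted_ss(yc, trial_basis) / tot_ss,
                                n, trial_basis.shape[1])
        if selected and trial_adj > full_adj:
            break                                   # second stopping rule
        selected.append(best)
        names.remove(best)
        basis = trial_basis
        resid = yc - basis @ (basis.T @ yc)
        rows.append({"variable": best, "added_r2": added[best],
                     "cum_adj_r2": trial_adj, "p": p})
    steps = pd.DataFrame(rows, columns=["variable", "added_r2", "cum_adj_r2", "p"])
    return ForwardSelectionResult(selected, steps, full_adj)
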