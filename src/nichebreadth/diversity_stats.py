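"""Alpha diversity, Bray-Curtis beta diversity, PCoA, ANOSIM and one-way
group comparisons with compact letter displays.

Alpha estimators: observed richness, bias-corrected Chao1
``S + F1(F1-1)/(2(F2+1))``, Shannon entropy in nats, and Gini-Simpson
``1 - sum p^2``. ANOSIM follows Clarke's rank formulation with statistic
``R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)``
and a one-sided permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, rankdata
from skbio import DistanceMatrix
from skbio.diversity import alpha as skalpha
from skbio.stats import ordination as skord

__all__ = [
    "alpha_diversity", "bray_curtis", "pcoa", "anosim", "group_compare",
    "OrdinationResult", "DistanceMatrix",
]


def alpha_diversity(table) -> pd.DataFrame:
    """Per-sample observed richness, Chao1, Shannon (nats) and Gini-Simpson."""
    sums = table.sample_sums()
    if np.any(sums <= 0):
        raise ValueError(f"empty sample(s): {list(table.sample_ids[sums <= 0])}")
    rows = []
    for j in range(table.n_samples):
        col = table.counts[:, j]
        rows.append({
            "observed": int(np.count_nonzero(col)),
            "chao1": float(skalpha.chao1(col, bias_corrected=True)),
            "shannon": float(skalpha.shannon(col, base=np.e)),
            "simpson": float(skalpha.simpson(col)),
        })
    return pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample_id"))


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities among samples."""
    x = table.counts.T.astype(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    empty_pairs = (x.sum(axis=1) == 0)
    if empty_pairs.sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")),
                          ids=list(table.sample_ids))


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates, eigenvalues, proportions."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix, negative_eigenvalue_policy: str = "drop"
         ) -> OrdinationResult:
    """Principal coordinates of a distance matrix.

    Gower-centres ``-0.5 * D**2`` and eigendecomposes; coordinates are
    eigenvectors scaled by sqrt(eigenvalue). Negative eigenvalues (from
    non-Euclidean D) are reported and, under the default policy, their
    axes dropped.
    """
    if negative_eigenvalue_policy not in ("drop", "keep-zeroed"):
        raise ValueError("policy must be 'drop' or 'keep-zeroed'")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = skord.pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    tol = max(abs(eig[0]), 1.0) * 1e-10
    neg = eig[eig < -tol]
    pos = eig > tol
    coords = res.samples.loc[:, pos.tolist()]
    coords.columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    coords.index = pd.Index(dm.ids, name="sample_id")
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig[pos],
        proportion_explained=res.proportion_explained.to_numpy()[pos],
        negative_eigenvalues=neg,
    )


def _anosim_r(condensed_ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    return (condensed_ranks[~within].mean() - condensed_ranks[within].mean()) \
        / (n * (n - 1) / 4.0)


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed=None,
           pairwise: bool = False):
    """Clarke's ANOSIM with permutation p-value.

    Returns ``(R, p)``; with ``pairwise=True`` additionally a DataFrame of
    group-pair tests. Ties in distances receive average ranks;
    ``p = (1 + #{R_null >= R}) / (1 + n_perm)``.
    """
    groups = np.asarray(groups)
    n = len(dm.ids)
    if groups.size != n:
        raise ValueError("one group label per sample required")
    uniq, sizes = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sizes < 2):
        raise ValueError(f"groups of size 1: {list(uniq[sizes < 2])}")
    rng = np.random.default_rng(seed)

    def _one(dmat: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
        m = dmat.shape[0]
        iu = np.triu_indices(m, k=1)
        ranks = rankdata(dmat[iu])
        r_obs = _anosim_r(ranks, labels[iu[0]] == labels[iu[1]], m)
        exceed = 0
        for _ in range(n_perm):
            lp = rng.permutation(labels)
            exceed += _anosim_r(ranks, lp[iu[0]] == lp[iu[1]], m) >= r_obs
        return r_obs, (1.0 + exceed) / (1.0 + n_perm)

    data = np.asarray(dm.data)
    r, p = _one(data, groups)
    if not pairwise:
        return r, p
    rows = []
    for i in range(uniq.size):
        for j in range(i + 1, uniq.size):
            sel = np.isin(groups, [uniq[i], uniq[j]])
            ri, pi = _one(data[np.ix_(sel, sel)], groups[sel])
            rows.append({"group1": uniq[i], "group2": uniq[j], "R": ri, "p": pi})
    return r, p, pd.DataFrame(rows)


def _compact_letters(names, sig_diff: set[tuple[str, str]]) -> dict[str, str]:
    # insert-and-absorb: split letter groups at each significant pair, then
    # drop groups contained in another
    sig = {frozenset(p) for p in sig_diff}
    letter_sets: list[set] = [set(names)]
    for pair in sig:
        a, b = tuple(pair)
        nxt = []
        for s in letter_sets:
            if a in s and b in s:
                nxt.extend([s - {a}, s - {b}])
            else:
                nxt.append(s)
        letter_sets = nxt
    letter_sets = [s for s in letter_sets
                   if s and not any(s < o for o in letter_sets)]
    # dedupe while keeping one of each
    seen, uniq_sets = set(), []
    for s in letter_sets:
        f = frozenset(s)
        if f not in seen:
            seen.add(f)
            uniq_sets.append(s)
    order = {g: i for i, g in enumerate(names)}
    uniq_sets.sort(key=lambda s: min(order[g] for g in s))
    out = {g: "" for g in names}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", uniq_sets):
        for g in sorted(s, key=order.get):
            out[g] += letter
    return out


def group_compare(values, groups, alpha: float = 0.05):
    """One-way ANOVA across groups plus a Tukey-HSD compact letter display.

    Returns ``(F, p, letters)`` where ``letters`` maps each group label to
    its letter string (groups not sharing a letter differ at ``alpha``).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq, sizes = np.unique(groups, return_counts=True)
    if uniq.size < 2 or np.any(sizes < 2):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    by_group = [values[groups == g] for g in uniq]
    if all(np.ptp(v) == 0 for v in by_group) and len({v[0] for v in by_group}) == 1:
        # identical constant data: F is 0/0; report the null outcome
        return 0.0, 1.0, {g: "a" for g in uniq}
    if all(np.ptp(v) == 0 for v in by_group):
        raise ValueError("zero within-group variance in every group")
    f_stat, p = f_oneway(*by_group)
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = list(combinations(tk.groupsunique, 2))  # statsmodels pair order
    sig = {pair for pair, rej in zip(pairs, tk.reject) if rej}
    letters = _compact_letters(list(uniq), sig)
    return float(f_stat), float(p), letters
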