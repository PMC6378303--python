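"""Levins' niche breadth, generalist/specialist classification, and
indicator-value (IndVal) confirmation of strict specialists.

For taxon *j* with relative abundances renormalised across the *n*
habitats so that sum_i p_ij = 1, Levins' breadth is

    B_j = 1 / sum_i p_ij**2

i.e. the effective number of habitats the taxon occupies (1 = confined to
a single site, n = perfectly even). Taxa with B above a high threshold
(default 8.7) are habitat generalists, below a low threshold (default 1.5)
habitat specialists, the remainder "other". Thresholds may instead be
derived from the outlier area (Tukey fences) of the observed B
distribution. Breadth-defined specialists with a significant IndVal > 0.3
are flagged as strict specialists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_io import AbundanceProfile, OTUTable, relative_abundances

CATEGORIES = ("generalist", "specialist", "other")


def levins_breadth(profile: AbundanceProfile | np.ndarray) -> np.ndarray:
    """Per-taxon Levins' B from a taxa x habitats relative-abundance matrix.

    Rows are renormalised per taxon; taxa absent everywhere get ``nan``.
    """
    values = profile.values if isinstance(profile, AbundanceProfile) else np.asarray(profile, float)
    if values.ndim != 2:
        raise ValueError("profile must be 2-D (taxa x habitats)")
    totals = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, values / totals, np.nan)
        b = 1.0 / np.square(p).sum(axis=1)
    b[totals[:, 0] <= 0] = np.nan
    return b


def classify_by_breadth(b_values: np.ndarray, low: float = 1.5,
                        high: float = 8.7) -> np.ndarray:
    """B > high -> generalist; B < low -> specialist; otherwise (including
    exact threshold hits) -> other. Inequalities are strict."""
    if not low < high:
        raise ValueError("low threshold must be below high threshold")
    b = np.asarray(b_values, dtype=float)
    out = np.full(b.shape, "other", dtype=object)
    out[b > high] = "generalist"
    out[b < low] = "specialist"
    out[~np.isfinite(b)] = "other"
    return out


def breadth_outlier_thresholds(b_values, n_samples: int | None = None
                               ) -> tuple[float, float]:
    """Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR) of the B distribution,
    clamped to the feasible range [1, n_samples].

    Quartiles use the linear-interpolation (type-7) definition.
    """
    b = np.asarray(b_values, dtype=float)
    b = b[np.isfinite(b)]
    if b.size < 5:
        raise ValueError("need at least 5 finite B values")
    q1, q3 = np.percentile(b, [25, 75])  # numpy default = linear interpolation
    iqr = q3 - q1
    if iqr == 0 and np.all(b == b[0]):
        raise ValueError("constant B distribution has no outlier area")
    low = max(q1 - 1.5 * iqr, 1.0)
    high = q3 + 1.5 * iqr
    if n_samples is not None:
        high = min(high, float(n_samples))
    return low, high


def indval(table: OTUTable, groups, n_perm: int = 999, seed=None) -> pd.DataFrame:
    """Dufrene-Legendre indicator values with permutation p-values.

    For taxon j and group g: specificity ``A = mean abundance in g / sum
    over groups of mean abundances`` and fidelity ``F = fraction of g's
    samples where the taxon occurs``; ``IndVal_j = max_g A*F``. The p-value
    counts random sample-to-group reassignments whose IndVal is at least
    the observed one: ``p = (1 + #{null >= obs}) / (1 + n_perm)``.
    """
    groups = np.asarray(groups)
    if groups.size != table.n_samples:
        raise ValueError("one group label per sample required")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(float)

    present = (counts.T > 0).astype(float)

    def _indval(member: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # member: float 0/1 matrix groups x samples
        gsize = member.sum(axis=1)
        means = (member @ counts.T) / gsize[:, None]          # groups x taxa
        denom = means.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(denom > 0, means / denom, 0.0)
        f = (member @ present) / gsize[:, None]
        iv = a * f
        best = iv.argmax(axis=0)
        return iv.max(axis=0), best

    member = np.vstack([groups == g for g in uniq]).astype(float)
    observed, best = _indval(member)
    exceed = np.zeros(table.n_taxa)
    for _ in range(n_perm):
        perm = rng.permutation(table.n_samples)
        null, _ = _indval(member[:, perm])
        exceed += null >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    absent = counts.sum(axis=1) == 0
    observed = np.where(absent, 0.0, observed)
    p = np.where(absent, 1.0, p)
    return pd.DataFrame({"indval": observed, "p": p,
                         "best_group": uniq[best]},
                        index=pd.Index(table.taxon_ids, name="taxon_id"))


def strict_specialists(categories: pd.Series, indval_result: pd.DataFrame,
                       min_indval: float = 0.3, alpha: float = 0.05) -> list[str]:
    """Breadth-defined specialists whose IndVal > min_indval at p < alpha."""
    spec = categories.index[categories == "specialist"]
    iv = indval_result.loc[spec]
    keep = (iv["indval"] > min_indval) & (iv["p"] < alpha)
    return list(iv.index[keep])


@dataclass
class NichePartition:
    """Full partition result: per-taxon B, category, IndVal and strict flag."""

    frame: pd.DataFrame     # index taxon_id; B, category, indval, p, strict
    thresholds: tuple[float, float]

    @property
    def categories(self) -> pd.Series:
        return self.frame["category"]

    def taxa_of(self, category: str) -> list[str]:
        if category == "all":
            return list(self.frame.index)
        return list(self.frame.index[self.frame["category"] == category])

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def partition_taxa(table: OTUTable, groups, low: float = 1.5, high: float = 8.7,
                   auto_thresholds: bool = False, n_perm: int = 999,
                   seed=None) -> NichePartition:
    """Classify every taxon of a (filtered, rarefied) table.

    ``groups`` drives the IndVal confirmation step (typically the gradient
    group labels, one per sample).
    """
    profile = relative_abundances(table)
    b = levins_breadth(profile.values.copy())
    if auto_thresholds:
        low, high = breadth_outlier_thresholds(b, table.n_samples)
    cats = classify_by_breadth(b, low, high)
    iv = indval(table, groups, n_perm=n_perm, seed=seed)
    frame = pd.DataFrame({"B": b, "category": cats},
                         index=pd.Index(table.taxon_ids, name="taxon_id"))
    frame = frame.join(iv[["indval", "p"]])
    strict = set(strict_specialists(frame["category"], iv))
    frame["strict"] = [t in strict for t in frame.index]
    return NichePartition(frame, (low, high))
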