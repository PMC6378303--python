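"""Beta-diversity null-model deviation.

Stochastically assembled communities are drawn from the regional species
pool: each sample keeps its observed total read count, and reads are drawn
multinomially with probabilities equal to the pooled (all-samples) relative
abundances. The null expectation of pairwise beta diversity is the mean
over many such assemblies, and the relative null deviation for a pair is

    (beta_obs - beta_null) / beta_obs

Deviations near zero mean the observed turnover is what random sampling
from a shared pool would produce (stochastic assembly); large positive
values mean communities are far more differentiated than the null
(deterministic, niche-driven assembly).

A richness-preserving variant (fixed per-sample richness, taxa chosen by
pool weights, reads spread over the chosen taxa) is available via
``mode="preserve_richness"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .community_io import OTUTable


def null_assemble(table: OTUTable, seed=None,
                  mode: str = "preserve_abundance") -> OTUTable:
    """One stochastic assembly of every sample from the regional pool."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("empty table")
    pool = table.taxon_sums().astype(float)
    total = pool.sum()
    if total <= 0:
        raise ValueError("table has no reads")
    probs = pool / total
    sums = table.sample_sums()
    if mode == "preserve_abundance":
        cols = [rng.multinomial(int(s), probs) for s in sums]
    elif mode == "preserve_richness":
        richness = (table.counts > 0).sum(axis=0)
        cols = []
        for s, k in zip(sums, richness):
            chosen = rng.choice(table.n_taxa, size=int(k), replace=False, p=probs)
            sub = probs[chosen] / probs[chosen].sum()
            col = np.zeros(table.n_taxa, dtype=np.int64)
            col[chosen] = 1                              # occupancy guaranteed
            extra = rng.multinomial(int(s) - int(k), sub)
            col[chosen] += extra
            cols.append(col)
    else:
        raise ValueError(f"unknown null model mode {mode!r}")
    return OTUTable(table.taxon_ids, table.sample_ids,
                    np.column_stack(cols), table.taxonomy)


@dataclass
class NullDeviationResult:
    pairs: pd.DataFrame      # sample_1, sample_2, beta_obs, beta_null_mean,
                             # beta_null_sd, deviation
    n_null: int
    beta_metric: str

    @property
    def deviations(self) -> np.ndarray:
        return self.pairs["deviation"].to_numpy()

    def mean_deviation(self) -> float:
        return float(np.nanmean(self.deviations))


def beta_null_deviation(table: OTUTable, n_null: int = 999, seed=None,
                        beta_metric: str = "braycurtis",
                        mode: str = "preserve_abundance") -> NullDeviationResult:
    """Observed vs null beta diversity for every sample pair.

    ``beta_null`` is the mean of the metric over ``n_null`` stochastic
    assemblies sharing one regional pool. Pairs with ``beta_obs = 0`` get
    ``nan`` deviation (flagged, not dropped).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    x = table.counts.T.astype(float)
    obs = pdist(x, metric=beta_metric)
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        null = null_assemble(table, rng, mode=mode)
        d = pdist(null.counts.T.astype(float), metric=beta_metric)
        acc += d
        acc2 += d * d
    null_mean = acc / n_null
    null_sd = np.sqrt(np.maximum(acc2 / n_null - null_mean ** 2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(obs > 0, (obs - null_mean) / obs, np.nan)
    n = table.n_samples
    iu = np.triu_indices(n, k=1)
    pairs = pd.DataFrame({
        "sample_1": table.sample_ids[iu[0]],
        "sample_2": table.sample_ids[iu[1]],
        "beta_obs": obs,
        "beta_null_mean": null_mean,
        "beta_null_sd": null_sd,
        "deviation": dev,
    })
    return NullDeviationResult(pairs, n_null, beta_metric)


def compare_deviation_groups(deviations: dict[str, np.ndarray], alpha: float = 0.05):
    """One-way ANOVA across named collections of deviation values.

    Returns ``(F, p, letters)`` via the shared group-comparison routine.
    """
    from .diversity_stats import group_compare

    names, values, labels = list(deviations), [], []
    for name in names:
        v = np.asarray(deviations[name], dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 finite deviations")
        values.append(v)
        labels.extend([name] * v.size)
    return group_compare(np.concatenate(values), np.asarray(labels), alpha=alpha)
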