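"""End-to-end pipeline: simulate or ingest an OTU table, preprocess,
partition taxa by niche breadth, and run the downstream community-assembly
analyses per subcommunity (all / generalists / specialists / other).

Every stochastic stage derives its own seed from the master seed via
``blake2b(master:stage)`` so stages are independent and the whole run is
reproducible bit-for-bit. All outputs are TSV; the run manifest (JSON)
records versions, parameters, seeds and per-stage dimensions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_io import (OTUTable, SampleMetadata, filter_rare, rarefy,
                           read_otu_table, relative_abundances)
from .diversity_stats import alpha_diversity, anosim, bray_curtis, group_compare, pcoa
from .matrix_tests import mantel, partial_mantel
from .niche_partition import partition_taxa
from .null_deviation import beta_null_deviation
from .ordination_vpa import hellinger, variation_partition
from .spatial_env import forward_select, geo_distance, pcnm
from .synthetic_data import SimulationConfig, simulate_metacommunity

log = logging.getLogger("nichebreadth")

SUBCOMMUNITIES = ("all", "generalist", "specialist", "other")
FLOAT_FMT = "%.10g"


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: first 4 bytes of blake2b('master:stage'),
    kept below 2**31."""
    h = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Run configuration; defaults follow the emulated study's parameters
    (depth 22310, rare-taxon threshold 2e-5, B thresholds 1.5/8.7, 999
    permutations and 999 null assemblies)."""

    seed: int = 0
    outdir: str = "results"
    otu_table: str | None = None
    metadata: str | None = None
    table_format: str = "tsv"
    simulation: dict | None = None
    depth: int = 22310
    filter_threshold: float = 2e-5
    low_threshold: float = 1.5
    high_threshold: float = 8.7
    auto_thresholds: bool = False
    indval_groups: str = "gradient"     # or "site"
    n_perm: int = 999
    n_null: int = 999
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__) - {"extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)


@dataclass
class ReportBundle:
    outdir: Path
    tables: dict[str, pd.DataFrame]
    manifest: dict


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = dict(config.simulation)
        sim.setdefault("seed", stage_seed(config.seed, "simulate"))
        simcfg = SimulationConfig.from_dict(sim)
        table, meta, truth = simulate_metacommunity(simcfg, seed=simcfg.seed)
        return table, meta, truth
    if config.otu_table is None or config.metadata is None:
        raise ValueError("config needs either a simulation block or "
                         "otu_table + metadata paths")
    table = read_otu_table(config.otu_table, config.table_format)
    meta = SampleMetadata.read_tsv(config.metadata)
    return table, meta, None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in dependency order and write all result tables."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "package": "nichebreadth",
        "version": __version__,
        "python": sys.version.split()[0],
        "master_seed": config.seed,
        "parameters": {
            "depth": config.depth, "filter_threshold": config.filter_threshold,
            "low_threshold": config.low_threshold,
            "high_threshold": config.high_threshold,
            "auto_thresholds": config.auto_thresholds,
            "indval_groups": config.indval_groups,
            "n_perm": config.n_perm, "n_null": config.n_null,
        },
        "stages": {},
    }

    def _stage(name, **info):
        manifest["stages"][name] = info
        log.info("stage=%s %s", name,
                 " ".join(f"{k}={v}" for k, v in info.items()))

    # ingest / simulate ---------------------------------------------------
    table, meta, truth = _load_inputs(config)
    meta = meta.align_to(table)
    _stage("ingest", n_taxa=table.n_taxa, n_samples=table.n_samples,
           simulated=truth is not None)

    # rarefy + rare-taxon filter -----------------------------------------
    if not np.all(table.sample_sums() == config.depth):
        table = rarefy(table, config.depth, seed=stage_seed(config.seed, "rarefy"))
        meta = meta.align_to(table)
    profile = relative_abundances(table)
    table, removed = filter_rare(profile, table, config.filter_threshold)
    _stage("preprocess", depth=config.depth, removed_rare=len(removed),
           n_taxa=table.n_taxa)

    # niche partition -----------------------------------------------------
    groups = meta.gradient if config.indval_groups == "gradient" else meta.sample_ids
    part = partition_taxa(table, groups,
                          low=config.low_threshold, high=config.high_threshold,
                          auto_thresholds=config.auto_thresholds,
                          n_perm=config.n_perm,
                          seed=stage_seed(config.seed, "indval"))
    tables["partition"] = part.frame
    counts = part.categories.value_counts().to_dict()
    _stage("partition", thresholds=part.thresholds, **counts)

    sub_tables = {"all": table}
    for cat in ("generalist", "specialist", "other"):
        taxa = part.taxa_of(cat)
        if taxa:
            sub_tables[cat] = table.subset_taxa(taxa)

    # spatial and environmental candidates (shared across subcommunities) -
    d_geo = geo_distance(meta)
    spatial = pcnm(d_geo)
    tables["pcnm_scores"] = spatial.scores
    env = meta.env
    env_std = (env - env.mean()) / env.std(ddof=1).replace(0.0, 1.0)
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix
    d_env = DistanceMatrix(squareform(pdist(env_std.to_numpy())),
                           ids=list(meta.sample_ids))
    _stage("spatial", n_pcnm=spatial.scores.shape[1],
           truncation=round(spatial.truncation, 3))

    alpha_rows, anosim_rows, pcoa_frames = [], [], []
    sel_rows, vpa_rows, mantel_rows, dev_rows = [], [], [], []
    grad = meta.gradient

    for name in SUBCOMMUNITIES:
        if name not in sub_tables:
            continue
        sub = sub_tables[name]
        # alpha diversity by gradient group, with ANOVA letters ----------
        adf = alpha_diversity(sub)
        for metric in adf.columns:
            try:
                f_stat, p, letters = group_compare(adf[metric].to_numpy(), grad)
            except ValueError:
                f_stat, p, letters = np.nan, np.nan, {g: "" for g in set(grad)}
            for g in sorted(set(grad)):
                vals = adf[metric].to_numpy()[grad == g]
                alpha_rows.append({
                    "subcommunity": name, "metric": metric, "gradient": g,
                    "mean": vals.mean(),
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)),
                    "anova_F": f_stat, "anova_p": p, "letter": letters[g]})
        # beta diversity, ordination, group separation -------------------
        dm = bray_curtis(sub)
        ord_res = pcoa(dm)
        coords = ord_res.coordinates.iloc[:, :2].copy()
        coords.insert(0, "subcommunity", name)
        pcoa_frames.append(coords.reset_index())
        r_global, p_global, pairwise_df = anosim(
            dm, grad, n_perm=config.n_perm,
            seed=stage_seed(config.seed, f"anosim:{name}"), pairwise=True)
        anosim_rows.append({"subcommunity": name, "group1": "(global)",
                            "group2": "(global)", "R": r_global, "p": p_global})
        for _, row in pairwise_df.iterrows():
            anosim_rows.append({"subcommunity": name, **row.to_dict()})
        # forward selection + VPA ----------------------------------------
        y = hellinger(sub.counts.T)
        yc = y - y.mean(axis=0, keepdims=True)
        sel_env = forward_select(yc, env_std, n_perm=config.n_perm,
                                 seed=stage_seed(config.seed, f"fsel_env:{name}"))
        sel_spa = forward_select(yc, spatial.scores, n_perm=config.n_perm,
                                 seed=stage_seed(config.seed, f"fsel_spa:{name}"))
        for kind, sel in (("env", sel_env), ("spatial", sel_spa)):
            for _, row in sel.steps.iterrows():
                sel_rows.append({"subcommunity": name, "set": kind,
                                 **row.to_dict()})
        x_env = env_std[sel_env.selected] if sel_env.selected else None
        x_spa = spatial.scores[sel_spa.selected] if sel_spa.selected else None
        if x_env is not None or x_spa is not None:
            vp = variation_partition(yc, x_env, x_spa, n_perm=config.n_perm,
                                     seed=stage_seed(config.seed, f"vpa:{name}"))
            vpa_rows.append({
                "subcommunity": name,
                "pure_env_pct": 100 * vp.pure_env,
                "pure_spatial_pct": 100 * vp.pure_spatial,
                "shared_pct": 100 * vp.shared,
                "unexplained_pct": 100 * vp.unexplained,
                "p_pure_env": vp.p_pure_env, "p_pure_spatial": vp.p_pure_spatial,
                "n_env_vars": 0 if x_env is None else x_env.shape[1],
                "n_spatial_vars": 0 if x_spa is None else x_spa.shape[1]})
        # Mantel tests ----------------------------------------------------
        for label, args in {
            "community~env": (dm, d_env, None),
            "community~space": (dm, d_geo, None),
            "community~env|space": (dm, d_env, d_geo),
            "community~space|env": (dm, d_geo, d_env),
        }.items():
            seed_m = stage_seed(config.seed, f"mantel:{name}:{label}")
            if args[2] is None:
                r, p = mantel(args[0], args[1], n_perm=config.n_perm, seed=seed_m)
            else:
                r, p = partial_mantel(*args, n_perm=config.n_perm, seed=seed_m)
            mantel_rows.append({"subcommunity": name, "comparison": label,
                                "r": r, "p": p, "n_perm": config.n_perm})
        # null deviation --------------------------------------------------
        nd = beta_null_deviation(sub, n_null=config.n_null,
                                 seed=stage_seed(config.seed, f"nulldev:{name}"))
        pairs = nd.pairs.copy()
        pairs.insert(0, "subcommunity", name)
        g1 = pd.Series(grad, index=table.sample_ids)
        pairs["gradient_pair"] = [
            "-".join(sorted([g1[a], g1[b]]))
            for a, b in zip(pairs["sample_1"], pairs["sample_2"])]
        dev_rows.append(pairs)
        _stage(f"subcommunity:{name}", n_taxa=sub.n_taxa,
               anosim_R=round(r_global, 4),
               mean_null_deviation=round(nd.mean_deviation(), 4))

    tables["alpha"] = pd.DataFrame(alpha_rows)
    tables["anosim"] = pd.DataFrame(anosim_rows)
    tables["pcoa_coords"] = pd.concat(pcoa_frames, ignore_index=True)
    tables["selected_vars"] = pd.DataFrame(
        sel_rows, columns=["subcommunity", "set", "variable", "added_r2",
                           "cum_adj_r2", "p"])
    tables["vpa"] = pd.DataFrame(vpa_rows)
    tables["mantel"] = pd.DataFrame(mantel_rows)
    tables["nulldev"] = pd.concat(dev_rows, ignore_index=True)

    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t",
                  float_format=FLOAT_FMT,
                  index=isinstance(df.index, pd.Index) and df.index.name is not None)
    manifest["elapsed_s"] = None  # excluded from outputs to keep runs byte-identical
    manifest["tables"] = {k: list(v.shape) for k, v in tables.items()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("pipeline finished in %.1fs", time.time() - t_start)
    return ReportBundle(outdir, tables, manifest)
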