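"""Gradient-metacommunity simulator with known assembly structure.

Emulates a 13-site elevational soil survey (2085-3051 m, three gradient
groups: low/medium/high) whose bacterial community contains three kinds of
taxa with known labels:

* **specialists** — narrow Gaussian responses to a latent gradient score
  (standardised elevation), so each is effectively confined to one habitat;
* **generalists** — essentially flat responses with mild site-to-site
  lognormal wobble, present everywhere;
* **neutral taxa** — no environmental response at all: site weights come
  from a regional lognormal abundance pool, modulated by distance-decaying
  dispersal from a random home site and strong idiosyncratic site noise.

Reads per sample are drawn multinomially at a fixed depth, so simulated
tables have the semantics of already-rarefied data. Environmental
covariates are generated per gradient group with means and dispersions
matching a subalpine soil survey (pH, soil temperature, water content,
conductivity, C and N pools) and within-group elevation trends whose signs
follow the across-group pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_io import OTUTable, SampleMetadata

# Site design: 13 elevations in three gradient groups (low 4 / medium 4 / high 5).
DEFAULT_ELEVATIONS = (2085.0, 2172.0, 2221.0, 2295.0,
                      2581.0, 2657.0, 2707.0, 2728.0,
                      2900.0, 2950.0, 3019.0, 3031.0, 3051.0)
DEFAULT_GROUPS = ("LEG",) * 4 + ("MEG",) * 4 + ("HEG",) * 5

# Per-group environmental summaries: variable -> {group: (mean, se_of_mean)}.
# Group sizes are LEG/MEG = 4, HEG = 5; per-site SD = se * sqrt(group size).
ENV_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "pH":     {"HEG": (5.85, 0.04),  "MEG": (5.86, 0.07),  "LEG": (6.32, 0.14)},
    "ST":     {"HEG": (12.39, 0.23), "MEG": (15.02, 0.23), "LEG": (18.12, 0.46)},
    "SWC":    {"HEG": (37.53, 1.86), "MEG": (42.61, 2.07), "LEG": (25.57, 3.52)},
    "EC":     {"HEG": (130.27, 10.22), "MEG": (97.50, 5.76), "LEG": (96.92, 10.33)},
    "TN":     {"HEG": (0.52, 0.02),  "MEG": (0.63, 0.05),  "LEG": (0.45, 0.03)},
    "TC":     {"HEG": (5.65, 0.22),  "MEG": (8.07, 0.41),  "LEG": (6.01, 0.27)},
    "CN":     {"HEG": (10.86, 0.17), "MEG": (13.41, 0.98), "LEG": (13.62, 0.50)},
    "SOC":    {"HEG": (41.68, 0.98), "MEG": (38.95, 1.31), "LEG": (38.51, 1.50)},
    "NH4_N":  {"HEG": (48.1, 2.72),  "MEG": (70.99, 2.40), "LEG": (49.8, 3.04)},
    "NO3_N":  {"HEG": (4.40, 0.16),  "MEG": (5.27, 0.42),  "LEG": (6.56, 0.40)},
    "NO2_N":  {"HEG": (1.48, 0.04),  "MEG": (1.47, 0.07),  "LEG": (1.48, 0.10)},
}

GROUP_SIZES = {"LEG": 4, "MEG": 4, "HEG": 5}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic metacommunity.

    Defaults mirror the emulated survey: 13 sites across three elevational
    gradient groups, 22310 reads per sample, and a 300/300/2400
    specialist/generalist/neutral split (~10%/10%/80% of taxa).

    Niche widths are in units of the standardised elevation score (SD = 1,
    span ~2.9): ``sigma_specialist`` = 0.02 keeps a specialist inside a
    single habitat even where neighbouring sites sit only tens of metres
    apart in elevation, while ``sigma_generalist`` = 30 is flat over the
    whole span. ``dispersal_decay`` is per metre of planar distance
    (default 0.15/km). Lognormal site noise (sigma) makes neutral taxa
    patchy without tying them to the gradient.
    """

    n_sites: int = 13
    elevations: tuple = DEFAULT_ELEVATIONS
    groups: tuple = DEFAULT_GROUPS
    n_specialist: int = 300
    n_generalist: int = 300
    n_neutral: int = 2400
    depth: int = 22310
    sigma_specialist: float = 0.02
    sigma_generalist: float = 30.0
    generalist_site_sd: float = 0.2
    neutral_site_sd: float = 1.2
    dispersal_decay: float = 0.15e-3
    abundance_sigma: float = 1.0
    # median relative mass of one taxon of each class before normalisation
    mean_height: dict = field(default_factory=lambda: {
        "specialist": 2.4, "generalist": 1.0, "neutral": 0.25})
    coords_mode: str = "transect"  # or "scattered"
    slope_grade: float = 0.10      # vertical/horizontal ratio for transect coords
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.elevations) != self.n_sites or len(self.groups) != self.n_sites:
            raise ValueError("elevations/groups must have n_sites entries")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (self.sigma_specialist < self.sigma_generalist):
            raise ValueError("specialist niche width must be below generalist width")
        if self.n_specialist + self.n_generalist + self.n_neutral == 0:
            raise ValueError("at least one taxon class must be non-empty")
        if self.coords_mode not in ("transect", "scattered"):
            raise ValueError(f"unknown coords_mode {self.coords_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown simulation keys: {sorted(extra)}")
        d = dict(d)
        for key in ("elevations", "groups"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Truth channel: per-taxon class labels, niche parameters, and the
    expected (noise-free, pre-multinomial) site compositions."""

    labels: pd.DataFrame          # index taxon_id; columns class, optimum, sigma
    expected: np.ndarray          # taxa x sites expected relative composition

    def taxa_of(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels["class"] == cls])

    def write_tsv(self, path) -> None:
        self.labels.to_csv(path, sep="\t")


def gaussian_niche_response(env_value, optimum, sigma, height=1.0):
    """Expected abundance ``height * exp(-(env-optimum)^2 / (2 sigma^2))``."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    if np.any(np.asarray(height) < 0):
        raise ValueError("height must be non-negative")
    dev = (np.asarray(env_value, dtype=float) - optimum) / sigma
    return height * np.exp(-0.5 * dev * dev)


def _site_frame(config: SimulationConfig) -> pd.DataFrame:
    elev = np.asarray(config.elevations, dtype=float)
    groups = np.asarray(config.groups, dtype=str)
    counters: dict[str, int] = {}
    ids = []
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        ids.append(f"{g}{counters[g]}")
    return pd.DataFrame({"sample_id": ids, "elevation_m": elev, "gradient": groups})


def simulate_env(sites: pd.DataFrame, seed=None) -> SampleMetadata:
    """Draw per-site environmental variables for a site table with
    ``sample_id``, ``elevation_m`` and ``gradient`` columns.

    Each variable is ``group mean + slope * (elevation - group mean
    elevation) + noise``: group means are hit exactly in expectation, and
    the within-group slope is the across-group trend of the three group
    means against their mean elevations, so monotone elevation signs carry
    through. Noise SD is the group SE scaled back to a per-site SD.
    """
    rng = np.random.default_rng(seed)
    for col in ("sample_id", "elevation_m", "gradient"):
        if col not in sites.columns:
            raise ValueError(f"sites table missing column {col!r}")
    groups = sites["gradient"].to_numpy(dtype=str)
    unknown = set(groups) - set(GROUP_SIZES)
    if unknown:
        raise ValueError(f"unknown gradient group label(s): {sorted(unknown)}")
    elev = sites["elevation_m"].to_numpy(dtype=float)
    out = sites.copy()
    uniq_groups = sorted(set(groups))  # fixed order so rng use is reproducible
    group_mean_elev = {g: elev[groups == g].mean() for g in uniq_groups}
    for var, stats in ENV_GROUP_STATS.items():
        gm = np.array([stats[g][0] for g in uniq_groups])
        ge = np.array([group_mean_elev[g] for g in uniq_groups])
        # across-group OLS slope of group means on group mean elevations
        slope = np.polyfit(ge, gm, 1)[0] if len(uniq_groups) > 1 else 0.0
        vals = np.empty(len(sites))
        for g in uniq_groups:
            m = groups == g
            mean, se = stats[g]
            site_sd = se * np.sqrt(GROUP_SIZES[g])
            centred = elev[m] - group_mean_elev[g]
            vals[m] = mean + slope * centred + rng.normal(0.0, site_sd, m.sum())
        out[var] = vals
    for col in ("x_m", "y_m"):   # coordinates are design inputs, not drawn here
        if col not in out.columns:
            out[col] = 0.0
    return SampleMetadata(out)


def _coordinates(config: SimulationConfig, elev: np.ndarray, rng) -> np.ndarray:
    if config.coords_mode == "scattered":
        return rng.uniform(0.0, 10_000.0, size=(elev.size, 2))
    x = (elev - elev.min()) / config.slope_grade
    y = rng.normal(0.0, 150.0, size=elev.size)
    return np.column_stack([x, y])


def simulate_metacommunity(config: SimulationConfig, seed=None
                           ) -> tuple[OTUTable, SampleMetadata, GroundTruth]:
    """Generate (counts, metadata, truth) for one gradient metacommunity.

    The latent habitat axis is the standardised elevation. Specialist
    optima sit at (slightly jittered) realised site positions on that axis
    — a niche optimum in an unoccupied gap would make the taxon
    unobservable by construction. Neutral site weights are
    ``pool_abundance * exp(-decay * distance_to_home) * lognormal noise``.
    Reads are multinomial at ``config.depth`` per site, so column sums are
    exact.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    sites = _site_frame(config)
    elev = sites["elevation_m"].to_numpy()
    z = (elev - elev.mean()) / elev.std(ddof=0)
    n_sites = config.n_sites

    coords = _coordinates(config, elev, rng)
    sites["x_m"], sites["y_m"] = coords[:, 0], coords[:, 1]
    meta = simulate_env(sites, rng)

    rows, ids, labels, optima, sigmas = [], [], [], [], []

    # specialists: narrow response around a home site's gradient score
    for k in range(config.n_specialist):
        h = config.mean_height["specialist"] * rng.lognormal(0.0, config.abundance_sigma)
        home = rng.integers(n_sites)
        opt = z[home] + rng.normal(0.0, config.sigma_specialist / 2)
        rows.append(gaussian_niche_response(z, opt, config.sigma_specialist, h))
        ids.append(f"SP{k + 1:05d}")
        labels.append("specialist")
        optima.append(opt)
        sigmas.append(config.sigma_specialist)

    # generalists: flat response + mild site wobble
    for k in range(config.n_generalist):
        h = config.mean_height["generalist"] * rng.lognormal(0.0, config.abundance_sigma)
        opt = rng.uniform(z.min(), z.max())
        base = gaussian_niche_response(z, opt, config.sigma_generalist, h)
        rows.append(base * rng.lognormal(0.0, config.generalist_site_sd, n_sites))
        ids.append(f"GN{k + 1:05d}")
        labels.append("generalist")
        optima.append(opt)
        sigmas.append(config.sigma_generalist)

    # neutral taxa: regional pool + dispersal decay + idiosyncratic noise
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for k in range(config.n_neutral):
        a = config.mean_height["neutral"] * rng.lognormal(0.0, config.abundance_sigma)
        home = rng.integers(n_sites)
        w = a * np.exp(-config.dispersal_decay * dmat[home])
        rows.append(w * rng.lognormal(0.0, config.neutral_site_sd, n_sites))
        ids.append(f"NT{k + 1:05d}")
        labels.append("neutral")
        optima.append(np.nan)
        sigmas.append(np.nan)

    weights = np.vstack(rows)
    col = weights.sum(axis=0)
    expected = weights / col
    counts = np.column_stack(
        [rng.multinomial(config.depth, expected[:, i]) for i in range(n_sites)])
    table = OTUTable(np.asarray(ids), meta.sample_ids, counts)
    truth = GroundTruth(
        pd.DataFrame({"class": labels, "optimum": optima, "sigma": sigmas},
                     index=pd.Index(ids, name="taxon_id")),
        expected)
    return table, meta, truth


def recovery_scores(truth: GroundTruth, predicted: pd.Series,
                    truth_class: str, predicted_class: str) -> dict[str, float]:
    """Precision/recall of a predicted category against a truth class,
    evaluated over the taxa that were actually classified (``predicted``'s
    index, i.e. the post-filter universe)."""
    universe = predicted.index
    truth_set = set(truth.labels.index[truth.labels["class"] == truth_class]) & set(universe)
    pred_set = set(predicted.index[predicted == predicted_class])
    tp = len(truth_set & pred_set)
    precision = tp / len(pred_set) if pred_set else np.nan
    recall = tp / len(truth_set) if truth_set else np.nan
    return {"precision": precision, "recall": recall,
            "n_true": len(truth_set), "n_predicted": len(pred_set)}
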