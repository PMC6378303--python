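# nichebreadth

Niche-breadth partitioning of microbial OTU tables and downstream
community-assembly inference along environmental gradients.

Soil bacterial communities along an elevational gradient contain taxa with
very different habitat requirements. This package implements the standard
workflow for asking *which assembly processes — deterministic environmental
selection or stochastic dispersal and drift — govern which taxa*:

1. **Niche breadth.** For each OTU *j*, Levins' index over the *n* sampled
   habitats,

   *B*<sub>j</sub> = 1 / Σ<sub>i</sub> *p*<sub>ij</sub>²,

   where *p*<sub>ij</sub> is OTU *j*'s relative abundance in habitat *i*
   renormalised so Σ<sub>i</sub> *p*<sub>ij</sub> = 1. *B* is the effective
   number of habitats occupied: 1 for a single-site taxon, *n* for a
   perfectly even one. OTUs with *B* above a high threshold (default 8.7)
   are **habitat generalists**, below a low threshold (default 1.5)
   **habitat specialists**, the rest "other taxa"; thresholds can also be
   derived from the outlier area (Tukey fences) of the observed *B*
   distribution. OTUs with mean relative abundance < 2×10⁻⁵ are removed
   first (undersampled taxa masquerade as specialists), and specialists are
   optionally confirmed by indicator-species analysis (IndVal > 0.3,
   permutation *P* < 0.05 → "strict specialists").
2. **Diversity and ordination.** α-diversity (observed richness,
   bias-corrected Chao1, Shannon, Gini–Simpson), Bray–Curtis β-diversity,
   PCoA, ANOSIM, one-way ANOVA with Tukey compact-letter displays.
3. **Space vs environment.** PCNM spatial eigenvectors, permutation-based
   forward selection, RDA/CCA, and variation partitioning of community
   variance into pure-environmental (E|S), pure-spatial (S|E), shared and
   unexplained fractions via Ezekiel-adjusted R²; Mantel and partial
   Mantel tests between community, environmental and geographic distances.
4. **β null deviation.** Stochastic communities are re-assembled from the
   regional species pool (per-sample totals preserved); the relative
   deviation (β_obs − β_null)/β_obs separates deterministic (large
   positive) from stochastic (near zero) assembly, per subcommunity.

Because the workflow is usually applied to sequencing data that cannot be
bundled, the package ships a **synthetic gradient-metacommunity generator**
that emulates a 13-site, three-gradient-group (HEG/MEG/LEG) elevational
survey — specialists with narrow Gaussian niches on the latent gradient,
near-flat generalists, neutrally assembled taxa with dispersal decay, and
soil covariates (pH, temperature, water content, C/N pools) whose group
means and elevation trends follow the emulated survey — with full ground
truth, so every stage is testable end to end.

## Worked example

```python
from nichebreadth import (SimulationConfig, simulate_metacommunity,
                          filter_rare, partition_taxa, beta_null_deviation)

cfg = SimulationConfig(seed=42)           # 13 sites, 300/300/2400 taxa
table, meta, truth = simulate_metacommunity(cfg)
table, removed = filter_rare(None, table)
print(f"retained {table.n_taxa} OTUs after the 2e-5 filter "
      f"({len(removed)} removed)")

part = partition_taxa(table, meta.gradient, n_perm=199, seed=1)
print(part.categories.value_counts().to_string())

for cat in ("generalist", "specialist"):
    sub = table.subset_taxa(part.taxa_of(cat))
    nd = beta_null_deviation(sub, n_null=199, seed=2)
    print(f"{cat}: mean beta null deviation = {nd.mean_deviation():.3f}")
```

prints

```
retained 2892 OTUs after the 2e-5 filter (108 removed)
category
other         2294
generalist     327
specialist     271
generalist: mean beta null deviation = 0.303
specialist: mean beta null deviation = 0.677
```

Read: ~9–11% of retained OTUs classify as specialists and generalists
each. Both subcommunities sit above the stochastic expectation, but the
specialists' β-diversity deviates far more — their turnover between sites
is driven by environmental selection, while the generalists' is much
closer to what random assembly from the shared regional pool produces.

## Command line

The `nba` tool wraps the library; every subcommand takes
`--config FILE --outdir DIR --seed N` (YAML key-value config, TSV
outputs):

```bash
nba simulate  --config examples/fixture_config.yaml --outdir out/
nba partition --config my_run.yaml        # B, category, IndVal, strict flag
nba diversity --config my_run.yaml        # alpha, Bray-Curtis, PCoA, ANOSIM
nba spatial   --config my_run.yaml        # PCNM axes + forward selection
nba vpa       --config my_run.yaml        # variation partitioning (percent)
nba mantel    --config my_run.yaml [--partial env|space]
nba nulldev   --config my_run.yaml --n-null 999
nba run       --config examples/fixture_config.yaml   # full pipeline
```

`nba run` executes every stage in dependency order for the whole community
and for each subcommunity (all / generalists / specialists / other) and
writes nine result tables plus a manifest sufficient to reproduce the run
bit-for-bit; all per-stage seeds derive from the master seed.

Input tables are TSV (rows = taxa, first column `#OTU_ID`, optional
trailing `taxonomy` column) or BIOM 2.x HDF5; metadata TSV needs
`sample_id, elevation_m, x_m, y_m, gradient` plus numeric environment
columns.

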