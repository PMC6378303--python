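# Methods

## Scope and model

The package partitions an OTU table into habitat generalists, specialists
and other taxa by Levins' niche breadth and then asks, per subcommunity,
how much of the community structure is explained by environmental
selection versus spatial/stochastic processes. The statistical machinery
is the standard community-ecology stack — Bray–Curtis/PCoA/ANOSIM,
PCNM + forward selection + (partial) RDA/CCA variation partitioning,
Mantel and partial Mantel tests, and β-diversity null models — wired
together so that one configuration file and one master seed reproduce a
whole analysis bit-for-bit.

### Niche breadth and classification

For OTU *j*, `levins_breadth` renormalises its relative abundances across
the *n* habitats (individual sampling sites) to sum to one and returns
B_j = 1/Σ_i p_ij². Taxa absent everywhere are flagged (B undefined)
rather than silently dropped. Classification uses strict inequalities:
B > high → generalist, B < low → specialist, anything else (including
values exactly at a threshold) → other. Defaults low = 1.5, high = 8.7;
`breadth_outlier_thresholds` instead derives the pair from Tukey fences
(Q1 − 1.5·IQR floored at 1, Q3 + 1.5·IQR capped at n) using type-7
(linear-interpolation) quartiles so the fence values are unambiguous.

Before classification, taxa with mean relative abundance below 2×10⁻⁵
(strictly below; equality is retained) are removed: at realistic depths a
taxon seen in a handful of reads is indistinguishable from a one-site
specialist. The filter is applied to the rarefied table by default — the
ordering of rarefaction and filtering is configurable because different
pipelines do it either way.

IndVal (Dufrêne–Legendre) confirms specialists: specificity
A = mean abundance in group / summed group means, fidelity F = occupancy
within the group, IndVal = max over groups of A·F, with
p = (1 + #{null ≥ obs})/(1 + n_perm) over random reassignments of samples
to groups. Breadth-specialists with IndVal > 0.3 and p < 0.05 are marked
"strict". The grouping unit defaults to the three gradient groups (the
13 individual sites are available via configuration); with single-sample
sites, site-level IndVal fidelity is always 0 or 1, which makes the
gradient grouping the informative default.

### Rarefaction

`rarefy` subsamples each sample's reads without replacement (multivariate
hypergeometric) to a common depth (default 22310), so column sums are
exact and a sample at exactly the target depth is returned unchanged.
Samples below depth are dropped with a warning by default; a flag turns
this into an error.

### Diversity

Alpha estimators delegate to scikit-bio: observed richness, bias-corrected
Chao1 S + F1(F1−1)/(2(F2+1)) (defined even when F2 = 0), Shannon entropy
in natural-log units, and Simpson reported as Gini–Simpson 1 − Σp² (the
form consistent with values ≈ 0.99 for diverse communities). ANOSIM uses
Clarke's rank formulation, R = (r̄_between − r̄_within)/(n(n−1)/4) with
average ranks for ties, giving R = 1 at perfect separation; p-values are
one-sided permutation tests of group labels. PCoA Gower-centres −½D² and
drops negative-eigenvalue axes by default (they are reported).

### Space, selection, variation partitioning

PCNM truncates the geographic distance matrix at the longest
minimum-spanning-tree edge (keeping the site graph connected), replaces
larger distances by 4× the truncation, and retains the
positive-eigenvalue PCoA eigenvectors as unit-norm spatial predictors
(scale-invariant, zero-mean, mutually orthogonal; axes agree with
vegan's `pcnm` to |r| = 1).

Forward selection is greedy on added constrained variance with double
stopping. The permutation statistic at each step is the **maximum added
R² over the remaining candidates**: under exchangeability this makes the
entry test exact at the first step regardless of how many candidates
compete, so with pure-noise candidates the probability of selecting
anything is ≈ α. (A per-candidate test would inflate type-I error roughly
k-fold; gating on a global test of the full candidate model is calibrated
too but loses all power when the candidate set nearly saturates the
sample size — with 13 sites and 11 environmental plus ~9 PCNM candidates,
that regime is the norm here.) Selection also stops once the cumulative
adjusted R² of the selected set would exceed the full candidate model's
(applied from the second variable on), and ties in added variance break
lexicographically by variable name for determinism.

RDA column-centres the (by default Hellinger-transformed) community
matrix, standardises X, drops numerically collinear columns with a
warning, and eigen-decomposes the fitted values; R² is the fitted share
of total sum of squares (constrained eigenvalues and R² agree with
vegan's `rda` to numerical precision). CCA performs the analogous
row-mass-weighted analysis on correspondence residuals; its total inertia
equals the contingency chi-square over the grand total. Variation
partitioning combines Ezekiel-adjusted R² of the env-only, space-only and
joint models: a = R²adj(joint) − R²adj(space), c = R²adj(joint) −
R²adj(env), b = R²adj(env) + R²adj(space) − R²adj(joint),
d = 1 − R²adj(joint). Adjusted R² may be negative and fractions are
reported unfloored so a + b + c + d = 1 holds exactly; the shared
fraction b is not a testable hypothesis and never receives a p-value.
Pure fractions are tested by permuting the residuals of the reduced
(conditioning) model.

### Mantel tests

Pearson correlation over the n(n−1)/2 sample pairs, one-sided (positive
association) permutation p by simultaneous row/column permutation of the
first matrix; the partial statistic is the first-order partial
correlation r₁₂·₃ recomputed per permutation. Community distance is
Bray–Curtis; environmental distance is Euclidean on standardised
variables; spatial distance is Euclidean on the planar coordinates. When
the control matrix is perfectly collinear with an input the partial
correlation is the 0/0 limit 0 (controlling for a copy of a matrix
removes the whole association).

### β null deviation

The null model preserves each sample's total read count and draws reads
multinomially from the pooled regional relative abundances (all samples
summed); per-sample richness is *not* preserved by default — a
richness-preserving variant is available behind `mode=
"preserve_richness"`. The null β for a pair is the mean Bray–Curtis over
n_null assemblies (default 999) from one shared pool, and the relative
deviation is (β_obs − β_null)/β_obs, in (−∞, 1], undefined (flagged) for
identical pairs. The denominator convention (β_obs) is one of several in
use; comparisons should therefore be made within a convention, which is
why the package treats subcommunity *orderings* of deviations, not their
absolute values, as the interpretable output.

## The synthetic metacommunity

The generator emulates the sampling design the analyses target: 13 sites
at fixed elevations 2085–3051 m in three gradient groups (low 4 /
medium 4 / high 5 sites), 22310 reads per sample (multinomial, so tables
are born rarefied), and a 300/300/2400 specialist/generalist/neutral
taxon split (~10%/10%/80%).

* **Latent gradient.** The habitat axis is the standardised elevation z.
  Observed soil variables (pH, ST, SWC, EC, TN, TC, C/N, SOC, NH4-N,
  NO3-N, NO2-N) are linear in elevation within groups — the slope being
  the across-group trend of the three group means — plus Gaussian site
  noise whose SD is the group SE scaled back to a per-site SD, so group
  means are matched exactly in expectation and the signs of elevation
  trends (pH, ST, NO3-N declining toward high elevation) carry through.
* **Specialists** get Gaussian responses with σ = 0.02 on z (≈ 7 m of
  elevation), with optima at slightly jittered *realised site positions*.
  Optima are anchored at sites rather than drawn uniformly because the
  high-elevation sites sit only tens of metres apart: a uniform optimum
  frequently lands in a habitat gap where the taxon is unobservable and
  removed by the rare-taxon filter, which would make "recovery of the
  specialist class" ill-posed rather than hard.
* **Generalists** get near-flat responses (σ = 30 ≫ gradient span)
  multiplied by mild lognormal site wobble (σ_site = 0.2), keeping their
  true B near n.
* **Neutral taxa** carry no environmental response: site weights are a
  regional lognormal abundance times exp(−decay·distance) dispersal from
  a random home site (default 0.15/km on transect coordinates laid out
  at 10% slope grade) times strong idiosyncratic lognormal site noise
  (σ = 1.2). The site-noise level is a deliberate design property: soil
  taxa vary over orders of magnitude between sites, and the noise must be
  large enough that neutral taxa read as "other" (B between the
  thresholds) rather than as spuriously even generalists — at σ = 1.0 a
  few percent of 2400 neutral taxa exceed B = 8.7 by chance and the
  generalist class stops being identifiable.
* Per-taxon abundances are lognormal (σ = 1) around class-specific
  medians (2.4/1.0/0.25) chosen so reads split roughly 45/45/10 between
  generalist, neutral and specialist mass.

`GroundTruth` carries labels, niche parameters and the expected
compositions, so tests can compute *true* niche breadths analytically.

What the generator does **not** emulate: sequence-level noise (PCR and
sequencing error, chimeras), phylogenetic correlation among taxa,
taxonomy, temporal variation, and any coupling between environmental
variables beyond their shared elevation trend. Passing recovery tests on
this generator therefore demonstrates that the statistical machinery
detects the structures it claims to detect at realistic sample sizes and
depths — not that real soil communities have those structures.

### Study conditions used by the checks

Two simulated regimes beyond the default appear in the test suite, chosen
once and fixed:

* *Assembly contrast*: 50 replicate metacommunities at a reduced size
  (100/100/400 taxa, depth 2000) — deviation orderings are insensitive to
  depth, and this keeps 50 full partition+null-model replicates fast.
* *Environment-only regime* (for the Mantel contrast): scattered (random)
  site coordinates, dispersal decay 0, and moderate niche widths
  (σ = 0.5, 200 niche taxa / 50 generalists / 200 neutral). Moderate
  widths matter: with σ = 0.02 every pair of sites is ~completely
  dissimilar, Bray–Curtis saturates, and no distance–decay signal exists
  for *any* Mantel test to detect. A gradual similarity decay is the
  regime in which "environment correlates with community, space does
  not" is a well-posed expectation.

## Numerical and design choices

* Quartiles: type-7 (numpy default); permutation p-values always
  (1 + exceed)/(1 + n_perm); all permutation tests take explicit seeds.
* Per-stage seeds derive from the master seed as the first four bytes of
  blake2b("master:stage") reduced below 2³¹ — stages are independent and
  the pipeline is byte-identical across runs and processes (group
  iteration orders are explicitly sorted; nothing consumes global RNG
  state).
* ANOSIM denominator n(n−1)/4 (Clarke); ties get average ranks.
* Collinear explanatory columns are pruned by sequential Gram–Schmidt
  with a 1e-9 relative tolerance.
* BIOM 2.x input is read directly from the HDF5 CSR layout (observation
  ids / sample ids / matrix) with h5py.
* The fixture pipeline configuration (`examples/fixture_config.yaml`)
  runs a 60/60/180-taxon, depth-1000 metacommunity with 99 permutations
  and 49 null assemblies; it exercises every stage in a couple of
  seconds and is the determinism reference.
* `scripts/acceptance.py` runs the default full-size design (3000 taxa,
  depth 22310) with 999 permutations and 999 null assemblies per
  subcommunity.

## Known limitations

* Two-set variation partitioning only (environment vs space); no
  three-way partitions or distance-based RDA.
* The null model family covers abundance-preserving and
  richness-preserving multinomial draws; incidence-based Raup–Crick and
  phylogenetic null models (βNTI, NST) are out of scope.
* With 13 sites, permutation tests bottom out at p = 1/(n_perm+1) and
  forward selection at n − 2 predictors; VPA requires the joint model to
  leave at least one residual degree of freedom.
* Mantel-type tests on distances induced by a common gradient are known
  to be conservative/anticonservative in edge regimes; the package
  reports them as the field uses them and leaves interpretation to the
  analyst.
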