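# Methods

`methanonet` implements the analysis chain used to ask whether biotic
factors (methanogen abundance, diversity, community structure, and the
complexity of their co-occurrence network) or abiotic soil properties
better explain the potential methane production rate (PMPR) of wetland
soils. This note documents the models, the synthetic-data generator that
stands in for field data, the numerical choices, and the known limits of
what the tests demonstrate.

## Potential methane production rates

A soil slurry is incubated anaerobically in a sealed serum vial and the
headspace CH4 mixing ratio `c` is measured at two time points. With the
headspace treated as an ideal gas,

    PMPR = (dc/dt) · M · (V_H · P_A) / (R · (T_ST + T)) / W_s

where `dc/dt` is the mixing-ratio change per day (mmol mol⁻¹ d⁻¹ or ppm
d⁻¹; a unit flag selects the scale), `M` = 16.04 g mol⁻¹ the molar mass
of CH4, `V_H` the headspace volume (L), `P_A` the atmospheric pressure
(kPa), `R` = 8.314 J mol⁻¹ K⁻¹, `T_ST` = 273.15 K, `T` the incubation
temperature (°C) and `W_s` the soil dry weight (g). The output is in
ng CH4 g⁻¹ (dry weight) d⁻¹. Replicate vials sharing a sample id are
averaged; when an N2-only control vial is present its flux is subtracted
by default (a policy flag disables this). `V_H` is always an explicit
input — it is never inferred from vial nominal volumes.

## Community stage

Count tables are sample-by-ASV integer matrices. ASVs with fewer than 10
reads summed over all samples are removed (the threshold is the total
across the dataset, not per sample). Samples are then rarefied to 1,016
reads by multivariate-hypergeometric subsampling (exact sampling without
replacement; deterministic given a seed). Richness and Shannon diversity
(natural log) are computed on the rarefied table; Bray–Curtis
dissimilarity on rarefied counts feeds the multivariate stage.

PERMANOVA uses Anderson's pseudo-F computed from the Gower-centered
inner-product matrix `G = -½ J D² J`: with `H` the hat matrix of the
design (group indicators or a numeric model matrix), F = [tr(HG)/df_a] /
[(tr(G) − tr(HG))/df_w]; the p-value is (1 + #{F_perm ≥ F_obs})/(1 +
n_perm) under row/column permutation of `G`. Permutations numerically
tied with the observed statistic (relative tolerance 1e-10) count as
exceeding, so relabelings equivalent to the observed grouping are never
dropped by floating-point noise.

Constrained analysis of principal coordinates (CAP / db-RDA) embeds the
dissimilarity matrix by principal coordinates, dropping negative-
eigenvalue axes (no Lingoes correction; the number dropped is reported).
Environmental columns are z-scored. Forward selection adds, at each
step, the candidate with the largest additional explained inertia among
those whose reduced-model residual-permutation p-value is ≤ 0.05, and
stops when none passes. Note the usual caveat of forward selection: with
k noise candidates the probability of selecting at least one is roughly
1 − 0.95^k, so the procedure is anti-conservative when many candidates
are screened; the tests therefore check null calibration with a single
candidate and only bound the multi-candidate rate.

The community index is a PCA of relative abundances (column-centered,
not scaled); PC1 and PC2 scores are carried into the path model (a flag
restricts the block to PC1). One-way ANOVA with Tukey's HSD produces a
compact letter display via insert-and-absorb over the significant-pair
graph, letters ordered by descending group mean.

## Co-occurrence networks

Networks are built per habitat (site) from the habitat's rarefied
samples. ASVs present in fewer than 20% of the habitat's samples are
excluded before correlating: rank correlations between mostly-absent
taxa are dominated by shared zero ties and are spurious. Spearman's rho
uses average ranks; p-values use the t approximation with n − 2 degrees
of freedom. An edge requires |rho| > 0.6 AND p < 0.01, both strict; no
multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists). Isolated nodes are dropped. Correlation networks are
undirected by construction.

Ten topological properties summarize a network: node count (NN), edge
count (NE), connectance NE/(NN·(NN−1)/2), average degree 2·NE/NN, global
clustering coefficient (transitivity), average local clustering
coefficient, average neighborhood connectivity (mean over nodes of the
mean degree of their neighbors; nodes without neighbors contribute 0),
average degree centrality AD/(NN−1), Freeman degree centralization
Σ(k_max − k_i)/((NN−1)(NN−2)), and the number of positively signed
edges. Networks with fewer than three nodes return 0 for the clustering
and centralization metrics and are flagged.

Each sample's subnetwork is the induced subgraph of its habitat network
on the ASVs with nonzero abundance in that sample. The complexity index
min–max standardizes each of the ten metrics across a sample set to
[0, 1] and averages them; metrics with zero range contribute 0 and are
flagged. The pipeline standardizes within each habitat by default
(`complexity_scope="habitat"`): subnetworks induced from different
habitat networks put the raw metrics on incomparable scales, and
experiments during development showed that with pooled standardization
the between-habitat component of the index is dominated by network-
inference noise rather than by any real between-habitat signal. Pooled
standardization across all samples remains available as a flag.

Keystones are classified from modules found by greedy modularity
maximization (deterministic for a given graph; method recorded in the
output). For node i in module s, z_i is the z-score of its within-module
degree among module members (zero when the module's degrees have no
spread) and the participation coefficient is p_i = 1 − Σ_s (k_is/k_i)².
Categories follow the four-quadrant rule with thresholds 2.5 and 0.62;
boundary values fall in the "≤" class. Isolated nodes get z_i = p_i = 0
and are flagged peripheral.

## Linking drivers to PMPR

Simple regressions report both the Pearson correlation on the
(optionally log10-transformed) fitted scale and Spearman's rho on raw
values; neither is privileged. Random-forest importance is the percent
increase in out-of-bag MSE when a feature is permuted within each tree's
out-of-bag rows, over a bagged ensemble of regression trees (p/3 feature
subsampling); significance comes from refitting the whole procedure on
permuted responses. Variation partitioning decomposes the response's
variance between a biotic and an abiotic predictor set using adjusted
R²: pure fractions are differences against the combined fit, the shared
fraction is the inclusion–exclusion remainder, and the four fractions
sum to one exactly; slightly negative fractions (an adjusted-R² 
artifact) are reported unclipped with a clipped display copy.

The PLS path model uses reflective (mode A) blocks: Nutrition {TOC, TN},
Non-nutrition {pH, EC}, Abundance {log10 mcrA}, Diversity {richness,
Shannon}, Community {PC1, PC2}, Complexity {complexity index}, and CH4
production {PMPR}. Both soil blocks point at the four biotic blocks, and
all six point at CH4 production. Estimation alternates the outer
approximation (indicator weights proportional to covariance with the
block's inner estimate) with the inner approximation (centroid scheme:
neighboring scores weighted by the sign of their correlation; a
factorial option uses the correlation itself) until the largest weight
change is below 1e-6 (at most 300 iterations; non-convergence raises).
Latent scores are fixed to unit variance with the sign chosen so each
block correlates positively with its indicators in aggregate. Path
coefficients are per-endogenous-block OLS on the latent scores; indirect
effects are sums of products over directed chains; GoF = sqrt(mean
communality × mean R²). Bootstrap resamples rows with replacement
(percentile CIs; stars at the 0.05/0.01/0.001 levels from the CI
excluding zero). Single-indicator blocks make the outer mode irrelevant,
and a single-path model with single indicators reduces exactly to the
Pearson correlation.

## The synthetic-data generator

The generator emulates the post-bioinformatics state of a four-wetland
survey: sites MQ and LQ are organic-rich, slightly acidic peatlands and
ZY and SGH saline-alkaline desert wetlands; 8 plots × 4 depth layers per
site give 128 samples (a flag drops a chosen number to mimic failed
libraries); ~300 ASVs; sequencing depths uniform in [1,800, 2,200] so
every sample survives rarefaction to 1,016.

Planted correlations are rank (Spearman) targets: a Gaussian copula with
correlation 2·sin(π·ρ/6) yields rank correlation ρ, and the log-normal
abundance map is monotone, so the plants are known exactly at the latent
level. Each site carries its own blocks (site-specific dominant taxa):

* **Core modules** (base 4 per site, with per-site offsets planting a
  network-size gradient: ZY 4, MQ and LQ 3, SGH 2): 10 members at equal
  baseline abundance, pairwise rank correlation 0.75, seven loading
  positively and three negatively on the module factor. The mixed signs
  matter: relative abundances lose any factor that dominates the
  community total (compositional closure), and a sign-balanced module
  keeps its factor out of the total. The negative loadings also produce
  genuinely negative edges.
* **Conditional associates** (2 per module): low-baseline taxa riding
  the same module factor through a steeper abundance map (σ = 1.6 vs 1.2
  for everything else), so they are solidly present when the module is
  active and absent otherwise. They attach to an existing clique, which
  makes subnetwork size and density move together when they appear.
* **A keystone star** per site: a hub correlated 0.66 with 10
  satellites that are only weakly correlated among themselves (0.50,
  below the edge threshold), so the detected star is hub-centered.
* **Background**: a common set (few zeros) and a rare set (below the
  occurrence filter). Intermediate-presence taxa are deliberately
  avoided — taxa present in 20–50% of samples generate unstable rank
  correlations through shared zero ties.

Soil properties are drawn per site around the site means with within-
site log-normal spreads (TOC 45%, reflecting strong depth gradients in
organic pools; TN tracks TOC stoichiometrically). log10 mcrA is normal
per site (site means 1.73–1.86, SD 0.12), bracketing the 1.6–2.0 decade.

The per-sample complexity driver is the number of planted-network taxa
present in the sample's counts, z-scored within its site — the sample's
realized share of its habitat's interaction network. PMPR is then

    PMPR = 65 + 10.0·z(log10 mcrA) + 6.0·z_nutr + 5.6·driver + N(0, 9)

in ng g⁻¹ d⁻¹, with z_nutr the mean of the TOC and TN z-scores. The
implied standardized direct effects are ≈ 0.60/0.36/0.33, ordered
abundance > nutrition > complexity. Incubation records (three replicates
plus an N2 control per sample; V_H = 0.115 L, P_A = 70 kPa as
appropriate for high-altitude sites, W_s = 5 g, 25 °C, days 1 → 15) are
back-computed by inverting the flux equation, so the flux module and the
generator check each other exactly.

## What the synthetic data do and do not show

The generator reproduces the features that matter to the methods —
compositional counts with realistic over-dispersion, site-specific
dominance, planted correlation blocks recoverable at the published
thresholds, and a known PMPR model — but not taxonomy, phylogeny,
chimeric artifacts, spatial autocorrelation within plots, or
depth-specific community structure (depth layers share their site's
network). Passing tests therefore demonstrate correctness of the
computations and recoverability of planted effects under these
conditions, not field-data effect sizes.

Three limits discovered while building the generator are worth stating
because they are properties of the method, not of the implementation:

1. **Keystone recovery through counts is weak.** A strict |rho| > 0.6
   filter at ~32 samples per network bounds what keystones can be
   planted: a node cannot correlate above the threshold with three or
   more mutually-uncorrelated modules (positive-semidefiniteness), so
   connector keystones cannot be planted at the count level at all, and
   star hubs hover near the z = 2.5 line. The Zi-Pi classifier itself is
   validated on synthetic graphs with planted connectors, where it
   recovers them reliably; count-level keystone recovery is reported by
   the acceptance script as the modest quantity it is.
2. **The ten-metric complexity index is nearly flat in subnetwork size
   for modular graphs**, because the density-type metrics (connectance,
   clustering, degree centrality) fall as the size-type metrics (nodes,
   edges, degree) rise. Its correlation with any per-sample driver that
   can be planted tops out near 0.45 under these conditions, which caps
   the statistical power of the complexity → PMPR regression; at n = 128
   the regression detects the planted effect in well under half of
   replicate surveys even though the planted effect is real. The PLS
   path ordering (abundance > nutrition > complexity) is nonetheless
   recovered essentially always, because it only requires the fitted
   complexity path to stay smallest.
3. **Between-habitat comparisons of the index are not meaningful**, as
   discussed above; hence the per-habitat standardization default.

## Problem sizes and determinism

Default analyses use the full 128-sample survey. The test suite scales
some replicate counts down to keep a full run near a few minutes: the
PERMANOVA calibration uses 1,000 null datasets of 20 samples with 99
permutations; edge recovery averages 20 replicate surveys; full-chain
properties use 100 replicate surveys with the PLS model fitted without
bootstrap; bootstrap coverage uses 40 replicates at 200 resamples. Every
random operation takes an explicit seed; the pipeline derives per-stage
seeds from the global seed and a CRC of the stage name, so stages are
independently reproducible and a rerun of a config is bit-identical.
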