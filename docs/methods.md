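# Methods

This note documents the models and procedures implemented in `cryoassembly`,
the choices made where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

The central object is a rarefied ASV feature table: non-negative integer
counts, samples × taxa in memory, taxa × samples on disk (classic QIIME
orientation). Rarefaction draws reads without replacement (multivariate
hypergeometric) to a uniform depth; samples below the target depth are
dropped and reported, not padded. The default depth is the minimum sample
sum, so nothing is dropped unless a depth is forced. Sample metadata carries
coordinates (lat ∈ [−90, 90], lon ∈ (−180, 180]), a continent group, a
glacier id, the Human Development Index (HDI ∈ [0, 1]), and five climate
covariates (wind speed U, solar radiation MSR, monthly temperature MMT,
precipitation TMP, vapor pressure VP). The phylogeny is a rooted tree with
branch lengths covering all table taxa.

## Diversity

Shannon entropy uses the natural log (the convention of the vegan R
ecosystem); `H ≤ ln(richness)` always. Bray–Curtis is Σ|x−y| / Σ(x+y);
Sørensen is Bray–Curtis on presence/absence, and the two are tested for
exact agreement on binarized data. PCoA is classical scaling: double-centre
−½D², eigendecompose, order axes by eigenvalue. Negative eigenvalues
(non-Euclidean dissimilarities) are reported with their total magnitude but
contribute no coordinates; no Lingoes/Cailliez correction is applied by
default. Proportion explained is relative to the positive-eigenvalue total.

Group differences in alpha diversity use Kruskal–Wallis with tie correction
followed by Dunn's z tests on pooled ranks; pairwise p-values are
Holm-adjusted (uniformly at least as powerful as Bonferroni at the same
family-wise error rate). The compact letter display covers the
"not significantly different" graph with maximal cliques, so groups sharing
a letter are statistically indistinguishable at the chosen alpha.

## Geography and distance decay

Site distances are haversine great-circle distances on a sphere of radius
6371.0088 km (IUGG mean). Geodesic (ellipsoidal) corrections are below 0.5%
and irrelevant at metacommunity scale. Distance decay is fit by OLS of
pairwise **dissimilarity** on distance (so limited dispersal gives a
positive slope), per region and pooled. Because the m(m−1)/2 pairs from m
samples are not independent, the primary p-value permutes sample labels of
the community matrix (999 permutations by default, slope as statistic,
one-sided for decay); the parametric OLS p is also reported for
comparability with published regressions.

## Assembly-process partitioning

**βMNTD.** For samples a, b with within-sample relative abundances f and
patristic distances d:

βMNTD(a,b) = ½ [ Σ_{i∈a} f_i · min_{j∈b} d(i,j) + Σ_{j∈b} f_j · min_{i∈a} d(i,j) ]

Abundance weighting is the default (an unweighted variant, equal weight per
present taxon, is available behind a flag). A taxon present in both samples
finds itself at distance 0, so identical communities score 0.

**βNTI.** The null shuffles taxon labels across the tree's tips —
equivalently, applies one random permutation to the rows and columns of the
patristic matrix — leaving community data untouched. One permutation per
replicate is shared by all sample pairs (999 replicates by default).
βNTI = (βMNTD_obs − mean_null)/sd_null. If the null has zero spread (e.g. a
star phylogeny, or two samples with identical taxon sets), βNTI is
undefined: the pair is reported as NaN/`undefined` and excluded from
process fractions rather than forced into a class.

**RC_bray.** Null communities preserve each sample's observed richness and
read depth: membership is drawn without replacement with probability
proportional to taxon occupancy across samples; each drawn taxon receives
one read (membership means presence), and the remaining reads are allocated
multinomially with probability proportional to regional-pool relative
abundance. Without the one-read floor the null loses ~10% of its members to
multinomial zeros and is not consistent with its own generative model.
Occupancy and pool abundances default to the analysed table but can be
supplied from a larger reference survey. RC = 2·[(#null < obs) + ½(#null = obs)]/n_null − 1, so −1 means
far more similar than the null expectation and +1 far more dissimilar.

**Classification.** Selection first: βNTI ≤ −2 → homogeneous selection,
βNTI ≥ +2 → heterogeneous selection. Otherwise RC decides: > 0.95 dispersal
limitation, < −0.95 homogenizing dispersal, |RC| ≤ 0.95 undominated drift.
The published rule leaves the measure-zero boundaries ambiguous (and, read
literally, lets the drift band overlap homogenizing dispersal); here exact
|βNTI| = 2 goes to the selection side and exact |RC| = 0.95 to drift, making
the five classes a true partition of the plane. A property test checks the
partition on 10⁵ points against an independently coded rule.

**Scale units.** Pairs are binned by geographic distance into half-open
60-km units [60(k−1), 60k); units with fewer than 5 pairs (configurable)
are excluded, and each process's per-unit fraction is regressed on the unit
index. At least three populated units are required for a trend.

**pNST.** For each within-group pair the observed βMNTD D is compared to
its taxa-shuffle null mean E; the pair's stochasticity ratio is
min(D,E)/max(D,E) — 1 when observed phylogenetic turnover matches the null
expectation, approaching 0 under strong selection in either direction. The
group pNST is the mean over pairs, clamped to [0, 1]. The degenerate case
D = 0 (identical communities) is defined as 0, the deterministic extreme,
even if E is also 0. This is the normalized-stochasticity-ratio construction
applied to phylogenetic turnover; the exact normalization is pinned here
because the published description names the index without an equation.

## Driver attribution

Environmental data for glacier surveys exist per glacier, so factor analyses
run at glacier level: between-glacier community distance is the mean of
cross-sample dissimilarities, alpha diversity the within-glacier mean.

- **Mantel tests** use Pearson r of lower-triangle vectors with a one-sided
  permutation p. A scalar factor's "distance" is the absolute difference of
  z-scores.
- **db-RDA** embeds the community matrix by PCoA (positive axes), regresses
  the embedding on z-standardized predictors, and reports the constrained
  share of total inertia, per-axis proportions (SVD of the fitted matrix),
  Ezekiel-adjusted R², and a permutation p for the whole model. Collinear
  predictors (condition number > 1e10) are rejected with the offending
  columns named.
- **Random-forest importance** regresses the first constrained axis on the
  covariates with bagged regression trees (500 trees, mtry = ⌈p/3⌉ — the
  regression defaults of the randomForest R package). %IncMSE is the percent
  increase of pooled out-of-bag MSE when a predictor is permuted among each
  tree's OOB samples. Significance follows the rfPermute recipe: the forest
  is refit on permuted responses and each observed importance is ranked in
  its null distribution. The bagging loop is implemented directly over
  scikit-learn decision trees because OOB permutation importance is not
  exposed by the stock ensemble API.
- **Diversity–factor fits**: richness ~ |latitude| + latitude² (absolute
  latitude maps both hemispheres onto one gradient; a "hump" is a negative
  quadratic term with an interior vertex) and richness ~ HDI by simple OLS.

PERMANOVA and ANOSIM (with seeds) are delegated to scikit-bio; PERMANOVA R²
is recovered from the pseudo-F via the sums-of-squares identity
R² = [1 + (n−k)/((k−1)F)]⁻¹, with R² = 1 when F is infinite (zero
within-group variance).

## Synthetic metacommunity generator

The generator defines the study conditions for all simulation-based tests.
Expected abundance of taxon t at site i is

pool_t · exp(−s_i (niche_t − env_i)²) · exp(−d(i, source_t)/L) · exp(a · hdi_i · 1[t anthropogenic])

with the selection, dispersal, and deposition factors switched on according
to the regime; counts are drawn multinomially at exactly the configured
depth, so rarefaction is a no-op on synthetic data.

- **Phylogeny and niches.** A pure-birth (Yule, rate 1) tree; niche optima
  evolve by Brownian motion (variance 1 per unit branch length), giving the
  phylogenetic niche conservatism that βNTI's power relies on. Site
  environments map absolute latitude linearly onto the empirical niche
  range, so filtering always has grip regardless of tree height.
- **Selection strength** defaults to s = 1 (Gaussian niche breadth
  σ = 1/√2 on the Brownian niche scale, roughly a third of the regional
  niche spread). At 300 taxa and 2000 reads this leaves a median site
  richness near a third of the pool — strong but realistic filtering. When a
  `richness_peak_lat` is set, s is modulated by
  0.1 + ((|lat| − peak)/width)², relaxing selection near the focal latitude
  so richness peaks there.
- **Dispersal** assigns each taxon a random source site and applies an
  exponential kernel with e-folding distance L (default 500 km). A single
  fixed source per continent would produce no within-continent turnover, so
  per-taxon sources are used instead.
- **Geography.** Sites form `n_continents` clusters around hard-coded
  centres that are pairwise > 5000 km apart, with Gaussian within-cluster
  spread (default 300 km), assigned round-robin for balance.
- **Covariates.** The five climate covariates are continent-level Gaussian
  shifts (sd = `covariate_continent_sd`) plus unit site noise; setting the
  continent sd to 0 makes them pure site-level noise, which is how the
  driver-recovery tests obtain known-null covariates. HDI mirrors its
  real-world structure — declining toward polar latitudes
  (0.95 − 0.011·|lat|, clipped to [0, 1]) with continent shifts and site
  noise — because human development is spatially organized, and polar ice
  sheets sit at the floor of the index. The anthropogenic deposition effect
  multiplies the expected abundance of a random fifth of the taxa by
  exp(a · hdi).

**What the generator does not emulate:** sequencing error, chimeras, or
compositional biases of library preparation; temporal dynamics; uneven
sampling across continents; phylogenetic signal in dispersal ability;
spatially autocorrelated environments within continents. Passing
regime-recovery tests therefore demonstrates that the statistics respond to
the processes they target under clean conditions, not that they are robust
to every artefact of real surveys.

## Problem sizes and tolerances

Exact statistics (dissimilarities, βMNTD, Mantel r, ANOSIM R,
Kruskal–Wallis H, haversine) are checked against independent brute-force
implementations at 1e-10 on ≤ 10-sample toys. Null-model calibrations use
199 null replicates / permutations and 200 simulations; regime- and
driver-recovery experiments use 20 replicates of 16–40-site, 200–300-taxon
metacommunities at 2000 reads per site, sizes at which each replicate's
null-model pass completes in seconds while the regimes remain clearly
separable. Permutation p-values use the add-one convention
(b+1)/(m+1). All null models, permutation tests, and forests take explicit
seeds; the pipeline spawns per-stage sub-seeds from one master seed, and
reruns with the same configuration are byte-identical.

## Known limitations

- βNTI is undefined for pairs with degenerate nulls (identical supports or
  ultrametric star trees); such pairs are excluded rather than imputed.
- The RC null conditions on observed richness and occupancy, so it is
  calibrated against its own generative model, not against arbitrary
  community processes.
- db-RDA discards negative-eigenvalue (non-Euclidean) structure before
  regression; with strongly non-Euclidean dissimilarities the constrained
  proportion understates total structure.
- Random-forest %IncMSE divides by the pooled OOB MSE; values are therefore
  comparable within a model fit, not across responses with different noise
  levels.
- Glacier-level aggregation treats each glacier's samples as exchangeable;
  within-glacier spatial structure is ignored.
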