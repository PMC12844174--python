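# cryoassembly

Biogeography and community-assembly analysis for cryoconite bacterial
metacommunities.

Cryoconite — the dark sediment that accumulates in melt holes on glacier
surfaces — hosts dense bacterial communities sampled by 16S rRNA surveys
across every glaciated continent. A recurring question for these surveys is
*what assembles these communities*: deterministic environmental filtering,
dispersal limitation between glaciers, or ecological drift — and how the
answer shifts with spatial scale and with geographic, climatic, and
anthropogenic gradients. `cryoassembly` implements that full analysis as a
tested, reusable pipeline operating on three standard inputs: a rarefied ASV
feature table (taxa × samples TSV), a rooted phylogeny (newick), and a
per-sample metadata table (coordinates, continent, HDI, and climate
covariates).

## What it computes

**Diversity and structure.** Richness and Shannon entropy (natural log),
Bray–Curtis and Sørensen dissimilarities, principal coordinate analysis, and
group testing by Kruskal–Wallis with Dunn's post hoc letters, ANOSIM, and
PERMANOVA.

**Distance decay.** Great-circle (haversine) distances between sites and
per-region OLS of pairwise dissimilarity on distance, with Mantel-style
permutation p-values (pairs sharing a sample are not independent).

**Assembly-process partitioning.** For every sample pair, the between-
community mean nearest taxon distance

βMNTD = ½ [ Σᵢ fᵢ · minⱼ d(i, j) + Σⱼ fⱼ · minᵢ d(j, i) ]

(f = within-sample relative abundances, d = patristic distance) is compared
to a taxa-shuffle null to give the beta nearest-taxon index
βNTI = (βMNTD_obs − μ_null)/σ_null, and observed Bray–Curtis is ranked
within a richness- and depth-preserving null to give the Raup–Crick index
RC_bray ∈ [−1, 1]. Pairs are classified: homogeneous selection
(βNTI ≤ −2), heterogeneous selection (βNTI ≥ +2), dispersal limitation
(|βNTI| < 2, RC > 0.95), homogenizing dispersal (|βNTI| < 2, RC < −0.95),
or undominated drift. Process fractions are tracked in 60-km distance bins
with a linear trend per process, and a phylogenetic normalized stochasticity
ratio (pNST ∈ [0, 1], higher = more stochastic) summarises each sample
group.

**Driver attribution.** Glacier-level Mantel tests of community distance
against each covariate, distance-based redundancy analysis (db-RDA),
random-forest importance (%IncMSE with rfPermute-style permutation
p-values) of the first constrained axis, and quadratic richness~|latitude| /
linear richness~HDI regressions.

**Synthetic metacommunities.** A generator with selectable assembly regimes
(`selection`, `dispersal_limitation`, `drift`, `mixed`) produces feature
tables, phylogenies with Brownian niche signal, geography clustered into
continents, and covariates with known ground truth, so every stage above is
testable without external data.

## Worked example

```python
import pandas as pd
from cryoassembly import ScenarioConfig, simulate_metacommunity
from cryoassembly.phylo import patristic_distance_matrix
from cryoassembly.biogeography import geographic_distance_matrix
from cryoassembly import assembly as asm

ds = simulate_metacommunity(ScenarioConfig(
    n_sites=40, n_taxa=300, depth=2000,
    regime="dispersal_limitation", dispersal_decay_km=500,
    n_continents=1, continent_spread_km=400, seed=11))

pat = patristic_distance_matrix(ds.tree, ds.table.taxon_ids)
geo = geographic_distance_matrix(ds.metadata)
pairs = asm.assemble_pairs(ds.table, pat, geo_dm=geo, n_null=199, seed=11)

print(asm.process_fractions(pairs).round(3))
trend = asm.scale_trend(pairs, unit_km=60, min_pairs=5)
print(trend.fits.round(4))
```

```
       HoS    HeS     DL     HD     DR  n_pairs
all  0.008  0.024  0.791  0.063  0.114      780
  process   slope  intercept  r_squared  p_value
0     HoS  0.0001     0.0055     0.0016   0.8404
1     HeS -0.0004     0.0295     0.0100   0.6122
2      DL  0.0319     0.2815     0.5792   0.0000
3      HD -0.0179     0.3749     0.3142   0.0019
4      DR -0.0137     0.3086     0.2948   0.0028
```

Under a 500-km dispersal kernel, 79% of sample pairs are classified as
dispersal-limited, and the DL fraction rises by ~3.2 percentage points per
60-km scale unit (R² = 0.58, p < 10⁻⁵) while homogenizing dispersal and
drift shrink — the expected scale signature of dispersal-limited assembly.

A full pipeline run (simulate → rarefy → diversity → decay → assembly →
drivers) is available from the command line:

```bash
cryoassembly all --seed 5 --out out/ --n-null 199
```

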