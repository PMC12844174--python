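"""Synthetic metacommunity generator with known assembly regimes.

Real cryoconite surveys pool hundreds of 16S samples from public archives;
here the entire data structure — a rarefied ASV table over sites clustered
into continents, a taxon phylogeny carrying niche signal, and per-site
environmental covariates — is simulated under a selectable assembly regime
(environmental filtering, distance-limited dispersal, pure drift, or a
mixture), so that every downstream statistic can be validated against a
known generating process.

The generating model, per site i and taxon t:

    E[abundance_it]  proportional to  pool_t
                                      * exp(-s_i * (niche_t - env_i)^2)    [selection]
                                      * exp(-d(i, source_t) / L)           [dispersal]

with counts drawn multinomially at a fixed sequencing depth. ``pool_t`` is a
lognormal regional species-abundance distribution, ``niche_t`` evolves by
Brownian motion on a pure-birth phylogeny (so close relatives share niches),
``env_i`` maps site latitude onto the niche scale, ``s_i`` is the selection
strength (optionally weakened near a focal latitude to create a mid-latitude
richness peak), and ``L`` is the e-folding distance of the dispersal kernel
from each taxon's source site.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from cryoassembly.io import FeatureTable, write_feature_table, write_metadata
from cryoassembly.phylo import brownian_tip_values, write_tree

REGIMES = ("selection", "dispersal_limitation", "drift", "mixed")

# Cluster centres for up to 8 synthetic continents (lat, lon), chosen so every
# pair is > 5000 km apart; within-cluster spread stays well below that.
CONTINENT_CENTERS = (
    (67.0, -50.0),
    (46.0, 60.0),
    (30.0, 140.0),
    (-15.0, -72.0),
    (-72.0, 20.0),
    (55.0, -155.0),
    (-43.0, 170.0),
    (20.0, 10.0),
)

_KM_PER_DEGREE = 111.19493  # mean great-circle km per degree of latitude


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic metacommunity scenario.

    The defaults describe a desk-scale survey: 40 sites on 5 continents,
    300 taxa, 2000 reads per site. ``selection_strength`` is the inverse
    squared niche breadth (in Brownian-niche units); ``dispersal_decay_km``
    the e-folding distance of the dispersal kernel. ``hdi_effect`` adds an
    anthropogenic deposition signal: a fifth of the taxa respond
    multiplicatively to the site's Human Development Index.
    ``richness_peak_lat`` (degrees absolute latitude), when set, relaxes
    selection near that latitude so site richness peaks there.
    """

    n_sites: int = 40
    n_taxa: int = 300
    depth: int = 2000
    regime: str = "mixed"
    selection_strength: float = 1.0
    dispersal_decay_km: float = 500.0
    n_continents: int = 5
    continent_spread_km: float = 300.0
    seed: int = 0
    hdi_effect: float = 0.0
    richness_peak_lat: float | None = None
    richness_width_lat: float = 20.0
    covariate_continent_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("n_sites must be >= 4")
        if self.n_taxa < 8:
            raise ValueError("n_taxa must be >= 8")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        if self.dispersal_decay_km <= 0 or self.continent_spread_km <= 0:
            raise ValueError("dispersal_decay_km and continent_spread_km must be positive")
        if not 1 <= self.n_continents <= len(CONTINENT_CENTERS):
            raise ValueError(f"n_continents must be in [1, {len(CONTINENT_CENTERS)}]")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticDataset:
    """A simulated metacommunity plus the ground truth that generated it."""

    table: FeatureTable
    tree: dendropy.Tree
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(self.table, outdir / "table.tsv")
        write_tree(self.tree, outdir / "tree.nwk")
        write_metadata(self.metadata, outdir / "metadata.csv")
        serializable = {
            k: v for k, v in self.truth.items() if isinstance(v, (str, int, float, list, dict))
        }
        (outdir / "truth.json").write_text(json.dumps(serializable, indent=2))


def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Simulate a rooted pure-birth (Yule, rate 1) phylogeny with niche optima.

    Tips are labelled ``t001, t002, ...``; each leaf node carries a ``niche``
    attribute evolved by Brownian motion (variance 1 per unit branch length)
    along the tree. Deterministic for a given seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    first, second = dendropy.Node(), dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    birth_time = {id(first): 0.0, id(second): 0.0}
    active = [first, second]
    now = 0.0
    while len(active) < n_taxa:
        k = len(active)
        now += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.edge.length = now - birth_time[id(node)]
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        birth_time[id(left)] = birth_time[id(right)] = now
        active.extend([left, right])
    now += rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length = now - birth_time[id(node)]

    width = max(3, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(f"t{i + 1:0{width}d}")
    niches = brownian_tip_values(tree, rng)
    for leaf in tree.leaf_node_iter():
        leaf.niche = float(niches[leaf.taxon.label])
    return tree


def tip_niches(tree: dendropy.Tree) -> pd.Series:
    """Niche optima attached by :func:`simulate_tree`, as a label-indexed Series."""
    out = {}
    for leaf in tree.leaf_node_iter():
        if not hasattr(leaf, "niche"):
            raise AttributeError(f"tip {leaf.taxon.label} carries no niche annotation")
        out[leaf.taxon.label] = leaf.niche
    return pd.Series(out)


def _site_geography(config: ScenarioConfig, rng: np.random.Generator):
    continents = np.array([f"C{(i % config.n_continents) + 1}" for i in range(config.n_sites)])
    centers = np.array(CONTINENT_CENTERS[: config.n_continents])
    idx = np.array([i % config.n_continents for i in range(config.n_sites)])
    offsets_km = rng.normal(0.0, config.continent_spread_km, size=(config.n_sites, 2))
    lat = centers[idx, 0] + offsets_km[:, 0] / _KM_PER_DEGREE
    lat = np.clip(lat, -90.0, 90.0)
    lon = centers[idx, 1] + offsets_km[:, 1] / (_KM_PER_DEGREE * np.cos(np.radians(centers[idx, 0])))
    lon = ((lon + 180.0) % 360.0) - 180.0
    lon[lon == -180.0] = 180.0
    return continents, lat, lon


def _covariates(config: ScenarioConfig, continents, lat, rng: np.random.Generator) -> pd.DataFrame:
    n = len(continents)
    groups = pd.unique(continents)
    cov = {}
    for name in ("u", "msr", "mmt", "tmp", "vp"):
        base = {c: rng.normal(0.0, config.covariate_continent_sd) for c in groups}
        cov[name] = np.array([base[c] for c in continents]) + rng.normal(0.0, 1.0, n)
    # HDI mirrors its real-world spatial structure: human development declines
    # toward polar latitudes (polar ice sheets get ~0), plus country-level
    # shifts per continent and site noise.
    shift = {c: rng.normal(0.0, 0.1 * config.covariate_continent_sd) for c in groups}
    hdi = (
        0.95
        - 0.011 * np.abs(np.asarray(lat))
        + np.array([shift[c] for c in continents])
        + rng.normal(0.0, 0.08, n)
    )
    cov["hdi"] = np.clip(hdi, 0.0, 1.0)
    return pd.DataFrame(cov)


def simulate_metacommunity(config: ScenarioConfig) -> SyntheticDataset:
    """Simulate a full dataset (table, tree, metadata) under the configured regime."""
    master = np.random.default_rng(config.seed)
    tree_seed = int(master.integers(2**31))
    rng = np.random.default_rng(master.integers(2**31))

    tree = simulate_tree(config.n_taxa, seed=tree_seed)
    niches = tip_niches(tree)
    taxa = list(niches.index)

    continents, lat, lon = _site_geography(config, rng)
    cov = _covariates(config, continents, lat, rng)
    abs_lat = np.abs(lat)

    # Map absolute latitude onto the empirical niche scale so environmental
    # filtering always has grip regardless of tree height.
    lo, hi = niches.min(), niches.max()
    span = np.ptp(abs_lat)
    env = lo + (abs_lat - abs_lat.min()) / (span if span > 0 else 1.0) * (hi - lo)

    pool = rng.lognormal(0.0, 1.0, config.n_taxa)
    weights = np.tile(pool, (config.n_sites, 1)).astype(float)

    use_selection = config.regime in ("selection", "mixed")
    use_dispersal = config.regime in ("dispersal_limitation", "mixed")

    strength = np.full(config.n_sites, config.selection_strength)
    if config.richness_peak_lat is not None:
        strength = config.selection_strength * (
            0.1 + ((abs_lat - config.richness_peak_lat) / config.richness_width_lat) ** 2
        )
    if use_selection:
        weights *= np.exp(-strength[:, None] * (niches.to_numpy()[None, :] - env[:, None]) ** 2)

    source_site = rng.integers(config.n_sites, size=config.n_taxa)
    if use_dispersal:
        from cryoassembly.biogeography import haversine_km

        d_source = haversine_km(
            lat[:, None], lon[:, None], lat[source_site][None, :], lon[source_site][None, :]
        )
        weights *= np.exp(-d_source / config.dispersal_decay_km)

    anthro = rng.random(config.n_taxa) < 0.2
    if config.hdi_effect != 0.0:
        weights *= np.exp(config.hdi_effect * np.outer(cov["hdi"].to_numpy(), anthro.astype(float)))

    counts = np.empty((config.n_sites, config.n_taxa), dtype=np.int64)
    for i in range(config.n_sites):
        p = weights[i] / weights[i].sum()
        counts[i] = rng.multinomial(config.depth, p)

    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_sites)]
    table = FeatureTable(pd.DataFrame(counts, index=sample_ids, columns=taxa))
    metadata = pd.DataFrame(
        {
            "glacier_id": [f"G{i + 1:03d}" for i in range(config.n_sites)],
            "continent": continents,
            "lat": lat,
            "lon": lon,
            "hdi": cov["hdi"].to_numpy(),
            "u": cov["u"].to_numpy(),
            "msr": cov["msr"].to_numpy(),
            "mmt": cov["mmt"].to_numpy(),
            "tmp": cov["tmp"].to_numpy(),
            "vp": cov["vp"].to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = {
        "regime": config.regime,
        "config": asdict(config),
        "env": dict(zip(sample_ids, env.tolist())),
        "niches": niches.to_dict(),
        "source_site": dict(zip(taxa, (sample_ids[s] for s in source_site))),
        "anthropogenic_taxa": [t for t, a in zip(taxa, anthro) if a],
    }
    return SyntheticDataset(table=table, tree=tree, metadata=metadata, truth=truth)
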