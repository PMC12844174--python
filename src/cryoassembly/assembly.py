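"""Null-model partitioning of community assembly processes.

Implements the phylogenetic/taxonomic two-stage inference framework used in
microbial community ecology: the beta nearest-taxon index (betaNTI, the
standardized effect size of betaMNTD under a taxa-shuffle null) separates
deterministic selection (|betaNTI| > 2) from the rest, and the Bray-Curtis
Raup-Crick index (RCbray) splits the remainder into dispersal limitation
(RC > 0.95), homogenizing dispersal (RC < -0.95), and undominated
drift (|RC| <= 0.95). The phylogenetic normalized stochasticity ratio
(pNST) summarises, per group of samples, how close observed phylogenetic
turnover sits to its null expectation. The 60-km scale-unit analysis bins
sample pairs by geographic distance and regresses each process's relative
contribution on the scale-unit index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from cryoassembly.io import FeatureTable
from cryoassembly.phylo import patristic_distance_matrix

PROCESSES = ("HoS", "HeS", "DL", "HD", "DR")

BETA_NTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def _relative_abundances(table: FeatureTable, weighted: bool) -> tuple[np.ndarray, list[np.ndarray]]:
    counts = table.counts.to_numpy(dtype=float)
    sums = counts.sum(axis=1)
    if (sums == 0).any():
        empty = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"betaMNTD undefined for empty samples: {empty}")
    present = [np.flatnonzero(row > 0) for row in counts]
    if weighted:
        rel = counts / sums[:, None]
    else:
        rel = np.zeros_like(counts)
        for i, cols in enumerate(present):
            rel[i, cols] = 1.0 / len(cols)
    return rel, present


def _beta_mntd_all_pairs(rel: np.ndarray, present: list[np.ndarray], dist: np.ndarray) -> np.ndarray:
    """betaMNTD between every sample pair, given relative abundances and a
    taxon patristic matrix. For each community b, ``m_b[i]`` is taxon i's
    distance to its nearest taxon within b; betaMNTD(a,b) is the average of
    the abundance-weighted means of ``m_b`` over a and ``m_a`` over b.
    """
    n_samples = rel.shape[0]
    nearest = np.empty((n_samples, dist.shape[0]))
    for b, cols in enumerate(present):
        nearest[b] = dist[:, cols].min(axis=1)
    cross = rel @ nearest.T
    return 0.5 * (cross + cross.T)


def beta_mntd(
    table: FeatureTable,
    tree: dendropy.Tree | pd.DataFrame,
    weighted: bool = True,
) -> pd.DataFrame:
    """Observed betaMNTD for all sample pairs (symmetric, zero diagonal).

    ``tree`` may be a dendropy tree or a precomputed patristic DataFrame.
    Abundance weighting uses within-sample relative abundances; the
    unweighted variant gives every present taxon equal weight.
    """
    if isinstance(tree, pd.DataFrame):
        dist = tree.loc[table.taxon_ids, table.taxon_ids].to_numpy()
    else:
        dist = patristic_distance_matrix(tree, table.taxon_ids).to_numpy()
    rel, present = _relative_abundances(table, weighted)
    out = _beta_mntd_all_pairs(rel, present, dist)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class BetaNTIResult:
    observed: pd.DataFrame  # betaMNTD
    beta_nti: pd.DataFrame  # standardized effect size; NaN where null sd = 0
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    degenerate: bool  # True if any off-diagonal null sd was 0


def beta_nti(
    table: FeatureTable,
    tree: dendropy.Tree | pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> BetaNTIResult:
    """betaNTI for all sample pairs under the taxa-shuffle null.

    Each null replicate permutes taxon labels across the tree's tips
    (equivalently, permutes rows/columns of the patristic matrix) while
    holding the community data fixed; the same permutation is applied to all
    pairs within a replicate. betaNTI = (obs - null mean) / null sd. Pairs
    whose null distribution has zero spread get NaN and set ``degenerate``.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if isinstance(tree, pd.DataFrame):
        dist = tree.loc[table.taxon_ids, table.taxon_ids].to_numpy()
    else:
        dist = patristic_distance_matrix(tree, table.taxon_ids).to_numpy()
    rel, present = _relative_abundances(table, weighted)
    obs = _beta_mntd_all_pairs(rel, present, dist)

    rng = np.random.default_rng(seed)
    n_taxa = dist.shape[0]
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_all_pairs(rel, present, dist[np.ix_(perm, perm)])
        delta = null - mean
        mean += delta / (r + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / (n_null - 1)) if n_null > 1 else np.zeros_like(obs)

    with np.errstate(divide="ignore", invalid="ignore"):
        nti = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    off_diag = ~np.eye(len(obs), dtype=bool)
    degenerate = bool((sd[off_diag] == 0).any())
    if degenerate:
        warnings.warn("null betaMNTD has zero spread for some pairs; betaNTI undefined there", stacklevel=2)
    ids = table.sample_ids
    wrap = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return BetaNTIResult(wrap(obs), wrap(nti), wrap(mean), wrap(sd), degenerate)


def rc_bray(
    table: FeatureTable,
    n_null: int = 999,
    seed: int = 0,
    reference: FeatureTable | None = None,
) -> pd.DataFrame:
    """Raup-Crick index on Bray-Curtis for all sample pairs, in [-1, 1].

    Null communities preserve each sample's observed richness and read
    depth: taxa are drawn without replacement with probability proportional
    to their occupancy across samples; each drawn taxon receives one read
    (it is present by construction) and the remaining reads are allocated
    multinomially with probability proportional to regional-pool relative
    abundance. RC is the rank of the observed Bray-Curtis within the null
    distribution, rescaled so that -1 means "far more similar than null"
    and +1 "far more dissimilar than null".

    By default occupancy and pool abundances come from ``table`` itself;
    pass ``reference`` to score a sample subset against a larger survey's
    regional pool.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts.to_numpy(dtype=np.int64)
    n_samples, n_taxa = counts.shape
    if reference is not None:
        missing = [t for t in table.taxon_ids if t not in reference.counts.columns]
        if missing:
            raise ValueError(f"reference table lacks taxa: {missing}")
        ref = reference.counts[table.taxon_ids].to_numpy(dtype=np.int64)
    else:
        ref = counts
    occupancy = (ref > 0).sum(axis=0).astype(float)
    pool = ref.sum(axis=0).astype(float)
    if (pool > 0).sum() < 2:
        raise ValueError("regional pool is degenerate (fewer than 2 taxa observed)")
    occ_prob = occupancy / occupancy.sum()
    richness = (counts > 0).sum(axis=1)
    depths = counts.sum(axis=1)

    obs = pdist(counts.astype(float), metric="braycurtis")
    rng = np.random.default_rng(seed)
    less = np.zeros_like(obs)
    equal = np.zeros_like(obs)
    taxon_idx = np.arange(n_taxa)
    for _ in range(n_null):
        null = np.zeros((n_samples, n_taxa))
        for s in range(n_samples):
            chosen = rng.choice(taxon_idx, size=richness[s], replace=False, p=occ_prob)
            probs = pool[chosen] / pool[chosen].sum()
            null[s, chosen] = 1 + rng.multinomial(depths[s] - richness[s], probs)
        null_bc = pdist(null, metric="braycurtis")
        less += null_bc < obs - 1e-12
        equal += np.abs(null_bc - obs) <= 1e-12
    rc = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    ids = table.sample_ids
    out = np.zeros((n_samples, n_samples))
    out[np.triu_indices(n_samples, k=1)] = rc
    out = out + out.T
    return pd.DataFrame(out, index=ids, columns=ids)


def classify_process(beta_nti_value, rc_value):
    """Map a (betaNTI, RCbray) pair to its assembly-process label.

    Selection dominates when |betaNTI| >= 2 (negative: homogeneous, HoS;
    positive: heterogeneous, HeS). Otherwise RCbray decides: > 0.95 is
    dispersal limitation (DL), < -0.95 homogenizing dispersal (HD), and
    |RC| <= 0.95 undominated drift (DR). Boundary values go to the
    selection side and to DR respectively, making the five classes a
    partition of the plane. Accepts scalars or arrays.
    """
    b = np.asarray(beta_nti_value, dtype=float)
    r = np.asarray(rc_value, dtype=float)
    if np.isnan(b).any() or np.isnan(r).any():
        raise ValueError("classify_process requires finite betaNTI and RCbray")
    out = np.full(np.broadcast(b, r).shape, "DR", dtype=object)
    b, r = np.broadcast_arrays(b, r)
    out[(np.abs(b) < BETA_NTI_THRESHOLD) & (r > RC_THRESHOLD)] = "DL"
    out[(np.abs(b) < BETA_NTI_THRESHOLD) & (r < -RC_THRESHOLD)] = "HD"
    out[b <= -BETA_NTI_THRESHOLD] = "HoS"
    out[b >= BETA_NTI_THRESHOLD] = "HeS"
    if out.ndim == 0:
        return str(out[()])
    return out


def assemble_pairs(
    table: FeatureTable,
    tree: dendropy.Tree | pd.DataFrame,
    geo_dm=None,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Run the full per-pair null-model analysis.

    Returns one row per unordered sample pair with betaMNTD, betaNTI,
    RCbray, the process label, and (if a geographic matrix is given) the
    pair's distance in km.
    """
    master = np.random.default_rng(seed)
    nti_seed, rc_seed = (int(s) for s in master.integers(2**31, size=2))
    nti = beta_nti(table, tree, n_null=n_null, seed=nti_seed, weighted=weighted)
    rc = rc_bray(table, n_null=n_null, seed=rc_seed)
    ids = table.sample_ids
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            bnti = nti.beta_nti.loc[a, b]
            rcv = rc.loc[a, b]
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "geo_km": float(geo_dm[a, b]) if geo_dm is not None else np.nan,
                    "beta_mntd": float(nti.observed.loc[a, b]),
                    "beta_nti": float(bnti),
                    "rc_bray": float(rcv),
                    "process": classify_process(bnti, rcv) if np.isfinite(bnti) else "undefined",
                }
            )
    return pd.DataFrame(rows)


def process_fractions(pairs: pd.DataFrame, grouping: pd.Series | None = None) -> pd.DataFrame:
    """Relative contribution of each assembly process, overall or per group.

    ``grouping``, if given, maps each pair (by row position or index) to a
    group label. Fractions sum to 1 per group; empty groups are excluded.
    """
    labelled = pairs[pairs["process"].isin(PROCESSES)]
    if labelled.empty:
        raise ValueError("no classified pairs")
    if grouping is None:
        grouping = pd.Series("all", index=labelled.index)
    else:
        grouping = grouping.reindex(labelled.index)
    rows = {}
    for g, sub in labelled.groupby(grouping.to_numpy()):
        fracs = sub["process"].value_counts(normalize=True)
        rows[g] = {p: float(fracs.get(p, 0.0)) for p in PROCESSES} | {"n_pairs": len(sub)}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ScaleTrend:
    """Per-60-km-unit process fractions plus linear trends across units."""

    units: pd.DataFrame  # unit_index, unit_lo_km, unit_hi_km, n_pairs, frac_* columns
    fits: pd.DataFrame  # process, slope, intercept, r_squared, p_value


def scale_trend(pairs: pd.DataFrame, unit_km: float = 60.0, min_pairs: int = 5) -> ScaleTrend:
    """Bin pairs into distance scale units and fit each process's trend.

    Unit k covers the half-open interval [unit_km*(k-1), unit_km*k). Units
    with fewer than ``min_pairs`` pairs are excluded; at least 3 populated
    units are required for a trend. Each process's per-unit fraction is
    regressed (OLS) on the unit index.
    """
    usable = pairs[np.isfinite(pairs["geo_km"]) & pairs["process"].isin(PROCESSES)].copy()
    usable["unit_index"] = (usable["geo_km"] // unit_km).astype(int) + 1
    unit_rows = []
    for k, sub in usable.groupby("unit_index"):
        if len(sub) < min_pairs:
            continue
        fracs = sub["process"].value_counts(normalize=True)
        unit_rows.append(
            {
                "unit_index": int(k),
                "unit_lo_km": unit_km * (k - 1),
                "unit_hi_km": unit_km * k,
                "n_pairs": len(sub),
            }
            | {f"frac_{p}": float(fracs.get(p, 0.0)) for p in PROCESSES}
        )
    units = pd.DataFrame(unit_rows)
    if len(units) < 3:
        raise ValueError(f"only {len(units)} populated scale units; trend needs >= 3")
    fit_rows = []
    for p in PROCESSES:
        y = units[f"frac_{p}"].to_numpy()
        x = units["unit_index"].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            fit_rows.append({"process": p, "slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0, "p_value": 1.0})
            continue
        fit = stats.linregress(x, y)
        fit_rows.append(
            {
                "process": p,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r_squared": float(fit.rvalue**2),
                "p_value": float(fit.pvalue),
            }
        )
    return ScaleTrend(units=units, fits=pd.DataFrame(fit_rows))


def pnst(
    table: FeatureTable,
    tree: dendropy.Tree | pd.DataFrame,
    groups: pd.Series,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.Series:
    """Phylogenetic normalized stochasticity ratio per sample group, in [0, 1].

    For every within-group pair, the observed betaMNTD D is compared to its
    taxa-shuffle null expectation E; the pair's stochasticity is the ratio
    min(D, E) / max(D, E), which is 1 when observed turnover matches the
    null (pure stochasticity) and approaches 0 under strong selection in
    either direction (including the degenerate D = 0 case of identical
    communities). The group value is the mean over its pairs. Groups with
    fewer than 3 samples are excluded with a warning.
    """
    groups = groups.reindex(table.sample_ids)
    result = {}
    for g in pd.unique(groups):
        members = [s for s, gg in groups.items() if gg == g]
        if len(members) < 3:
            warnings.warn(f"group {g!r} has fewer than 3 samples; excluded from pNST", stacklevel=2)
            continue
        sub = table.filter_samples(members).drop_empty_taxa()
        res = beta_nti(sub, tree, n_null=n_null, seed=seed, weighted=weighted)
        obs = res.observed.to_numpy()
        exp = res.null_mean.to_numpy()
        tri = np.triu_indices(len(members), k=1)
        d, e = obs[tri], exp[tri]
        hi = np.maximum(d, e)
        ratio = np.where(hi > 0, np.minimum(d, e) / np.where(hi > 0, hi, 1.0), 0.0)
        result[g] = float(np.clip(ratio.mean(), 0.0, 1.0))
    return pd.Series(result, name="pnst")
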