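"""Driver attribution: Mantel tests, db-RDA, PERMANOVA/ANOSIM, random-forest
importance, and diversity-factor regressions.

Environmental data for glacier surveys are collected per glacier, so all
factor analyses operate at glacier level: community dissimilarity between two
glaciers is the mean of their cross-sample dissimilarities, alpha diversity
the within-glacier mean, and covariates are taken from the glacier's
metadata row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.distance import permanova as _skbio_permanova
from sklearn.tree import DecisionTreeRegressor

from cryoassembly.io import COVARIATE_COLUMNS


# ---------------------------------------------------------------------------
# glacier-level aggregation
# ---------------------------------------------------------------------------

def aggregate_by_glacier(dm: DistanceMatrix, glacier: pd.Series) -> DistanceMatrix:
    """Mean cross-sample dissimilarity between glaciers (identity if 1:1)."""
    glacier = glacier.reindex(list(dm.ids))
    labels = list(pd.unique(glacier))
    data = np.asarray(dm.data)
    idx = {g: np.flatnonzero((glacier == g).to_numpy()) for g in labels}
    out = np.zeros((len(labels), len(labels)))
    for i, ga in enumerate(labels):
        for j in range(i + 1, len(labels)):
            block = data[np.ix_(idx[ga], idx[labels[j]])]
            out[i, j] = out[j, i] = block.mean()
    return DistanceMatrix(out, ids=[str(g) for g in labels])


def factor_distance(values: pd.Series) -> DistanceMatrix:
    """Environmental 'distance' for a scalar factor: |difference| of z-scores."""
    v = values.to_numpy(dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError(f"factor {values.name!r} is constant; distance undefined")
    z = (v - v.mean()) / sd
    return DistanceMatrix(np.abs(z[:, None] - z[None, :]), ids=[str(i) for i in values.index])


# ---------------------------------------------------------------------------
# matrix correlation and group tests (scikit-bio backed)
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    factor: str
    r: float
    p_value: float
    n_permutations: int


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "",
) -> MantelResult:
    """Mantel test: Pearson r of lower-triangle vectors, one-sided permutation p."""
    if list(dm_a.ids) != list(dm_b.ids):
        raise ValueError("distance matrices must share sample order")
    if dm_a.shape[0] < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    for name, dm in (("first", dm_a), ("second", dm_b)):
        if np.ptp(dm.condensed_form()) == 0:
            raise ValueError(f"{name} distance matrix is constant; r undefined")
    r, p, n = _skbio_mantel(
        dm_a, dm_b, method="pearson", permutations=n_permutations, alternative="greater", seed=seed
    )
    return MantelResult(factor=factor, r=float(r), p_value=float(p), n_permutations=n_permutations)


def mantel_factors(
    community_dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factors: tuple[str, ...] = COVARIATE_COLUMNS,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel test of the community matrix against each scalar factor."""
    rows = []
    rng = np.random.default_rng(seed)
    for f in factors:
        fd = factor_distance(metadata.loc[list(community_dm.ids), f].rename(f))
        res = mantel(community_dm, fd, n_permutations, seed=int(rng.integers(2**31)), factor=f)
        rows.append(vars(res))
    return pd.DataFrame(rows)


def permanova(dm: DistanceMatrix, groups: pd.Series, n_permutations: int = 999, seed: int = 0):
    """PERMANOVA (adonis-style): pseudo-F, R^2 = SS_between/SS_total, permutation p."""
    groups = groups.reindex(list(dm.ids))
    if groups.nunique() < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    res = _skbio_permanova(dm, groups.to_numpy(), permutations=n_permutations, seed=seed)
    f = float(res["test statistic"])
    n = dm.shape[0]
    k = groups.nunique()
    # invert pseudo-F to the SS decomposition: F = (SSb/(k-1)) / (SSw/(n-k));
    # infinite F means SSw = 0, i.e. perfect separation
    if np.isinf(f):
        r2 = 1.0
    elif np.isfinite(f):
        r2 = 1.0 / (1.0 + (n - k) / ((k - 1) * f))
    else:
        r2 = np.nan
    return {"pseudo_f": f, "r_squared": r2, "p_value": float(res["p-value"]), "n_permutations": n_permutations}


def anosim(dm: DistanceMatrix, groups: pd.Series, n_permutations: int = 999, seed: int = 0):
    """ANOSIM R in [-1, 1] with permutation p."""
    groups = groups.reindex(list(dm.ids))
    sizes = groups.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members each")
    res = _skbio_anosim(dm, groups.to_numpy(), permutations=n_permutations, seed=seed)
    return {"r": float(res["test statistic"]), "p_value": float(res["p-value"]), "n_permutations": n_permutations}


# ---------------------------------------------------------------------------
# distance-based redundancy analysis
# ---------------------------------------------------------------------------

@dataclass
class DbRdaResult:
    constrained_proportion: float  # share of total inertia explained by predictors
    axis_proportions: np.ndarray  # per constrained axis, of total inertia
    adjusted_r_squared: float
    p_value: float
    site_scores: pd.DataFrame  # samples x constrained axes (dbRDA1, ...)


def dbrda(
    community_dm: DistanceMatrix,
    predictors: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> DbRdaResult:
    """Distance-based redundancy analysis (PCoA followed by RDA).

    The community matrix is embedded by classical scaling (positive axes
    only); the embedding is regressed on z-standardized predictors. The
    constrained proportion is the share of total (positive) inertia carried
    by the fitted values; constrained axes come from an SVD of the fitted
    matrix. Adjusted R^2 uses Ezekiel's formula, and the overall model p is
    obtained by permuting predictor rows.
    """
    from cryoassembly.diversity import pcoa

    x = predictors.loc[list(community_dm.ids)].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than predictors ({p})")
    sd = x.std(axis=0, ddof=0)
    constant = [c for c, s in zip(predictors.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant predictor(s): {constant}")
    x = (x - x.mean(axis=0)) / sd
    if np.linalg.cond(x) > 1e10:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (predictors.columns[i], predictors.columns[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"collinear predictors (condition number > 1e10): {pairs or list(predictors.columns)}")

    ord_res = pcoa(community_dm)
    y = ord_res.coordinates.to_numpy()
    y = y - y.mean(axis=0)
    total_inertia = (y**2).sum()

    def constrained_ss(xmat: np.ndarray) -> tuple[float, np.ndarray]:
        beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
        fitted = xmat @ beta
        return (fitted**2).sum(), fitted

    ss_model, fitted = constrained_ss(x)
    r2 = ss_model / total_inertia
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm_ss, _ = constrained_ss(x[rng.permutation(n)])
        if perm_ss >= ss_model:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)

    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int((s > s[0] * 1e-9).sum()) if s.size else 0
    axis_prop = (s[:n_axes] ** 2) / total_inertia
    scores = pd.DataFrame(
        u[:, :n_axes] * s[:n_axes],
        index=list(community_dm.ids),
        columns=[f"dbRDA{i + 1}" for i in range(n_axes)],
    )
    return DbRdaResult(
        constrained_proportion=float(r2),
        axis_proportions=axis_prop,
        adjusted_r_squared=float(adj_r2),
        p_value=float(p_value),
        site_scores=scores,
    )


# ---------------------------------------------------------------------------
# random-forest importance with permutation significance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    importance: pd.DataFrame  # predictor, incmse_pct, p_value
    model_r_squared: float  # out-of-bag pseudo-R^2


def _forest_importances(x: np.ndarray, y: np.ndarray, n_trees: int, mtry: int, rng) -> tuple[np.ndarray, float]:
    """Bagged regression trees; returns %IncMSE per predictor and OOB R^2.

    %IncMSE is the percent increase of pooled out-of-bag MSE when a
    predictor is permuted among each tree's OOB samples.
    """
    n, p = x.shape
    mse_orig = np.zeros(n_trees)
    mse_perm = np.zeros((n_trees, p))
    oob_pred_sum = np.zeros(n)
    oob_pred_cnt = np.zeros(n)
    valid = np.zeros(n_trees, dtype=bool)
    for t in range(n_trees):
        boot = rng.integers(n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeRegressor(max_features=mtry, random_state=int(rng.integers(2**31)))
        tree.fit(x[boot], y[boot])
        pred = tree.predict(x[oob])
        oob_pred_sum[oob] += pred
        oob_pred_cnt[oob] += 1
        mse_orig[t] = np.mean((pred - y[oob]) ** 2)
        valid[t] = True
        for j in range(p):
            x_perm = x[oob].copy()
            x_perm[:, j] = x_perm[rng.permutation(oob.size), j]
            mse_perm[t, j] = np.mean((tree.predict(x_perm) - y[oob]) ** 2)
    base = mse_orig[valid].mean()
    inc = 100.0 * (mse_perm[valid].mean(axis=0) - base) / base
    seen = oob_pred_cnt > 0
    resid = y[seen] - oob_pred_sum[seen] / oob_pred_cnt[seen]
    var_y = y[seen].var()
    r2 = 1.0 - resid.var() / var_y if var_y > 0 else np.nan
    return inc, float(r2)


def rf_importance(
    response: pd.Series,
    predictors: pd.DataFrame,
    n_trees: int = 500,
    n_permutations: int = 100,
    seed: int = 0,
) -> ImportanceResult:
    """Random-forest variable importance (%IncMSE) with permutation p-values.

    The forest regresses the response (typically the first constrained
    db-RDA axis) on z-standardized predictors; importance is the percent
    increase in out-of-bag MSE when the predictor is permuted. Significance
    refits the forest on ``n_permutations`` permuted responses and ranks
    each observed importance within its null distribution.
    """
    y = response.to_numpy(dtype=float)
    if len(y) < 10:
        raise ValueError("random-forest importance needs at least 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    x = predictors.loc[response.index].to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    p = x.shape[1]
    mtry = max(1, int(np.ceil(p / 3)))
    rng = np.random.default_rng(seed)

    observed, r2 = _forest_importances(x, y, n_trees, mtry, rng)
    null = np.zeros((n_permutations, p))
    for b in range(n_permutations):
        null[b], _ = _forest_importances(x, rng.permutation(y), n_trees, mtry, rng)
    p_values = ((null >= observed[None, :]).sum(axis=0) + 1) / (n_permutations + 1)
    frame = pd.DataFrame(
        {"predictor": list(predictors.columns), "incmse_pct": observed, "p_value": p_values}
    ).sort_values("incmse_pct", ascending=False, ignore_index=True)
    return ImportanceResult(importance=frame, model_r_squared=r2)


# ---------------------------------------------------------------------------
# diversity ~ factor regressions
# ---------------------------------------------------------------------------

@dataclass
class FactorFits:
    latitude: dict  # quadratic richness ~ |lat|: coefficients, r_squared, p, vertex, hump
    hdi: dict  # linear richness ~ HDI: slope, intercept, r_squared, p


def diversity_factor_fits(alpha: pd.DataFrame, metadata: pd.DataFrame) -> FactorFits:
    """Quadratic richness~|latitude| and linear richness~HDI regressions.

    Latitude enters as absolute latitude so both hemispheres share one
    gradient; a 'hump' is a negative quadratic coefficient whose vertex lies
    strictly inside the observed latitude range. Observations are expected at
    glacier level (one row per glacier).
    """
    joined = alpha.join(metadata[["lat", "hdi"]], how="inner").dropna()
    if len(joined) < 5:
        raise ValueError("need at least 5 observations")
    rich = joined["richness"].to_numpy(dtype=float)
    abs_lat = np.abs(joined["lat"].to_numpy(dtype=float))
    hdi = joined["hdi"].to_numpy(dtype=float)
    for name, v in (("latitude", abs_lat), ("hdi", hdi)):
        if np.ptp(v) == 0:
            raise ValueError(f"constant predictor: {name}")

    x_quad = sm.add_constant(np.column_stack([abs_lat, abs_lat**2]))
    quad = sm.OLS(rich, x_quad).fit()
    c0, c1, c2 = quad.params
    vertex = -c1 / (2 * c2) if c2 != 0 else np.nan
    hump = bool(c2 < 0 and abs_lat.min() < vertex < abs_lat.max())
    lat_fit = {
        "intercept": float(c0),
        "linear": float(c1),
        "quadratic": float(c2),
        "r_squared": float(quad.rsquared),
        "p_value": float(quad.f_pvalue),
        "vertex_lat": float(vertex),
        "hump": hump,
        "n": len(joined),
    }

    lin = stats.linregress(hdi, rich)
    hdi_fit = {
        "slope": float(lin.slope),
        "intercept": float(lin.intercept),
        "r_squared": float(lin.rvalue**2),
        "p_value": float(lin.pvalue),
        "n": len(joined),
    }
    return FactorFits(latitude=lat_fit, hdi=hdi_fit)
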