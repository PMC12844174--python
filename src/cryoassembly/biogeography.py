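"""Geographic distances and distance-decay of community similarity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (broadcasting)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geographic_distance_matrix(metadata: pd.DataFrame) -> DistanceMatrix:
    """Pairwise haversine distances (km) between sample coordinates."""
    from cryoassembly.io import validate_coordinates

    validate_coordinates(metadata["lat"], metadata["lon"])
    lat = metadata["lat"].to_numpy(dtype=float)
    lon = metadata["lon"].to_numpy(dtype=float)
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(metadata.index))


@dataclass
class DecayFit:
    """OLS fit of pairwise community dissimilarity on geographic distance."""

    region: str
    slope: float  # dissimilarity per km
    intercept: float
    r_squared: float
    p_parametric: float
    p_permutation: float
    n_pairs: int


def _pair_vectors(comm: np.ndarray, geo: np.ndarray, idx: np.ndarray):
    sub_c = comm[np.ix_(idx, idx)]
    sub_g = geo[np.ix_(idx, idx)]
    tri = np.triu_indices(len(idx), k=1)
    return sub_c[tri], sub_g[tri]


def distance_decay(
    community_dm: DistanceMatrix,
    geo_dm: DistanceMatrix,
    groups: pd.Series | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-decay regressions per group plus an overall pooled fit.

    Each fit regresses within-group pairwise dissimilarity on pairwise
    distance. Because pairs sharing a sample are not independent, the
    primary p-value comes from a Mantel-style permutation of sample labels
    (slope as the test statistic, one-sided for positive decay); the plain
    parametric OLS p is reported alongside for comparability. Groups with
    fewer than 3 samples are skipped with a warning.
    """
    if list(community_dm.ids) != list(geo_dm.ids):
        raise ValueError("community and geographic matrices must share sample order")
    ids = list(community_dm.ids)
    comm, geo = np.asarray(community_dm.data), np.asarray(geo_dm.data)
    rng = np.random.default_rng(seed)

    regions: dict[str, np.ndarray] = {"overall": np.arange(len(ids))}
    if groups is not None:
        groups = groups.reindex(ids)
        for g in pd.unique(groups):
            regions[str(g)] = np.flatnonzero((groups == g).to_numpy())

    rows = []
    for region, idx in regions.items():
        if len(idx) < 3:
            warnings.warn(f"group {region!r} has fewer than 3 samples; skipped", stacklevel=2)
            continue
        y, x = _pair_vectors(comm, geo, idx)
        if np.ptp(x) == 0:
            warnings.warn(f"group {region!r} has no distance variation; skipped", stacklevel=2)
            continue
        fit = stats.linregress(x, y)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(idx))
            y_perm, _ = _pair_vectors(comm[np.ix_(idx, idx)][np.ix_(perm, perm)], geo[np.ix_(idx, idx)], np.arange(len(idx)))
            if stats.linregress(x, y_perm).slope >= fit.slope:
                exceed += 1
        p_perm = (exceed + 1) / (n_permutations + 1)
        rows.append(
            DecayFit(
                region=region,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=float(fit.rvalue**2),
                p_parametric=float(fit.pvalue),
                p_permutation=float(p_perm),
                n_pairs=len(x),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
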