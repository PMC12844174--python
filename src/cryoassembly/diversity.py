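"""Alpha diversity, community dissimilarity, ordination, and group tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, norm
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from cryoassembly.io import FeatureTable


def alpha_diversity(table: FeatureTable, warn_unequal: bool = True) -> pd.DataFrame:
    """Per-sample richness and Shannon entropy (natural log).

    Richness counts taxa with positive abundance; Shannon is
    ``-sum(p_i ln p_i)`` over those taxa. All-zero samples have no defined
    diversity and are excluded with a warning. Expects a rarefied table and
    warns if sample sums differ.
    """
    sums = table.sample_sums
    if warn_unequal and sums.nunique() > 1:
        warnings.warn("sample sums are unequal; alpha diversity is depth-sensitive", stacklevel=2)
    empty = list(sums.index[sums == 0])
    if empty:
        warnings.warn(f"excluding all-zero samples: {empty}", stacklevel=2)
    counts = table.counts.loc[sums > 0]
    arr = counts.to_numpy(dtype=float)
    p = arr / arr.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame(
        {"richness": (arr > 0).sum(axis=1), "shannon": -plogp.sum(axis=1)},
        index=counts.index,
    )


def _check_no_zero_pairs(table: FeatureTable) -> None:
    sums = table.sample_sums
    zero = list(sums.index[sums == 0])
    if len(zero) >= 2:
        raise ValueError(f"dissimilarity undefined between all-zero samples: {zero}")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    _check_no_zero_pairs(table)
    condensed = pdist(table.counts.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def sorensen(table: FeatureTable) -> DistanceMatrix:
    """Sørensen dissimilarity 1 - 2a/(2a+b+c); Bray-Curtis on presence/absence."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    _check_no_zero_pairs(table)
    binary = (table.counts.to_numpy() > 0).astype(float)
    condensed = pdist(binary, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) output."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, relative to positive total

    @property
    def negative_eigenvalue_magnitude(self) -> float:
        neg = self.eigenvalues[self.eigenvalues < 0]
        return float(-neg.sum())


def pcoa(dm: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis by double-centred eigendecomposition.

    Axes are ordered by eigenvalue; proportion explained is relative to the
    sum of positive eigenvalues. Negative eigenvalues (non-Euclidean input)
    are reported but contribute no coordinates; requesting more axes than
    there are positive eigenvalues truncates with a warning.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    gower = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    n_pos = int((eigvals > tol).sum())
    if k is None:
        k = n_pos
    if k > n_pos:
        warnings.warn(f"requested {k} axes but only {n_pos} positive eigenvalues; truncating", stacklevel=2)
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_total = eigvals[eigvals > tol].sum()
    prop = eigvals[:k] / pos_total if pos_total > 0 else np.zeros(k)
    frame = pd.DataFrame(coords, index=list(dm.ids), columns=[f"PCo{i + 1}" for i in range(k)])
    return OrdinationResult(coordinates=frame, eigenvalues=eigvals, proportion_explained=prop)


@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    dunn: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adjusted
    letters: dict[str, str]  # compact letter display per group


def kruskal_wallis_dunn(values, groups, alpha: float = 0.05, p_adjust: str = "holm") -> KruskalDunnResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise post hoc test.

    Dunn z statistics use the pooled-rank variance with tie correction;
    pairwise p-values are Holm-adjusted by default. The compact letter
    display mirrors the usual figure annotation: groups sharing a letter are
    not significantly different at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: values[groups == g] for g in labels}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = kruskal(*by_group.values())

    n = len(values)
    ranks = pd.Series(values).rank().to_numpy()
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            ra = ranks[groups == ga].mean()
            rb = ranks[groups == gb].mean()
            se = np.sqrt(var_base * (1.0 / (groups == ga).sum() + 1.0 / (groups == gb).sum()))
            z = (ra - rb) / se if se > 0 else 0.0
            rows.append((ga, gb, z, 2 * norm.sf(abs(z))))
    dunn = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    dunn["p_adjusted"] = multipletests(dunn["p_raw"], method=p_adjust)[1] if len(dunn) else []

    letters = _compact_letters(labels, dunn, alpha)
    return KruskalDunnResult(h_statistic=float(h), p_value=float(p), dunn=dunn, letters=letters)


def _compact_letters(labels, dunn: pd.DataFrame, alpha: float) -> dict[str, str]:
    # Cover the "not significantly different" graph by maximal cliques; each
    # clique gets one letter, so groups sharing a letter are indistinguishable.
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    for _, row in dunn.iterrows():
        if row["p_adjusted"] >= alpha:
            graph.add_edge(row["group_a"], row["group_b"])
    cliques = sorted(nx.find_cliques(graph), key=lambda c: sorted(labels.index(g) for g in c))
    letters: dict[str, str] = {g: "" for g in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for g in clique:
            letters[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(s)) for g, s in letters.items()}
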