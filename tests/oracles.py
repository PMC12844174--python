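"""Independent brute-force reference implementations used only by the tests.

Every function here is written as directly as possible from the defining
formula — explicit Python loops, no shared code with the package — so that
agreement between package and oracle is meaningful evidence of correctness.
"""

from __future__ import annotations

import math

import numpy as np


def bray_curtis_brute(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def sorensen_brute(x, y) -> float:
    sa = {i for i, v in enumerate(x) if v > 0}
    sb = {i for i, v in enumerate(y) if v > 0}
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    return 1 - 2 * a / (2 * a + b + c)


def beta_mntd_brute(counts_a, counts_b, dist) -> float:
    """Exhaustive nearest-taxon search, abundance-weighted."""
    fa = {i: v / sum(counts_a) for i, v in enumerate(counts_a) if v > 0}
    fb = {j: v / sum(counts_b) for j, v in enumerate(counts_b) if v > 0}
    term_a = sum(w * min(dist[i][j] for j in fb) for i, w in fa.items())
    term_b = sum(w * min(dist[i][j] for i in fa) for j, w in fb.items())
    return 0.5 * (term_a + term_b)


def mantel_r_brute(dm_a, dm_b) -> float:
    n = len(dm_a)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            xs.append(dm_a[i][j])
            ys.append(dm_b[i][j])
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    cov = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    vx = math.sqrt(sum((a - mx) ** 2 for a in xs))
    vy = math.sqrt(sum((b - my) ** 2 for b in ys))
    return cov / (vx * vy)


def haversine_cosine_brute(lat1, lon1, lat2, lon2, radius=6371.0088) -> float:
    """Spherical law of cosines — an independent great-circle formula."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dlon = math.radians(lon2 - lon1)
    cosc = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dlon)
    return radius * math.acos(min(1.0, max(-1.0, cosc)))


def kruskal_h_brute(groups) -> float:
    """Rank-sum H with tie correction, straight from the definition."""
    values = [v for g in groups for v in g]
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    n = len(values)
    pos = 0
    h = 0.0
    for g in groups:
        rsum = sum(ranks[pos : pos + len(g)])
        h += rsum**2 / len(g)
        pos += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in values:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def anosim_r_brute(dm, groups) -> float:
    n = len(dm)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dists = [dm[i][j] for i, j in pairs]
    order = sorted(range(len(dists)), key=lambda k: dists[k])
    ranks = [0.0] * len(dists)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and dists[order[j]] == dists[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    within = [r for r, (i, j) in zip(ranks, pairs) if groups[i] == groups[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if groups[i] != groups[j]]
    return (sum(between) / len(between) - sum(within) / len(within)) / (n * (n - 1) / 4)


def classify_brute(bnti, rc) -> str:
    """The five-way rule restated independently from its published wording."""
    if bnti <= -2:
        return "HoS"
    if bnti >= 2:
        return "HeS"
    if rc > 0.95:
        return "DL"
    if rc < -0.95:
        return "HD"
    return "DR"


def ols_brute(x, y):
    """Slope/intercept by the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
    return beta[1], beta[0]


def permanova_r2_brute(dm, groups) -> float:
    """R^2 = 1 - SSwithin/SStotal from squared distances (Anderson's identity)."""
    n = len(dm)
    ss_total = sum(dm[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(groups):
        idx = [i for i in range(n) if groups[i] == g]
        ss_within += sum(dm[i][j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    return 1 - ss_within / ss_total
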