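"""Independent brute-force oracles used to cross-check the package.

Everything here is written directly from first principles (textbook
formulas, exhaustive scans) and never calls the implementation under
test.
"""

import math

import numpy as np


def anova_oracle(groups):
    """One-way ANOVA F from the raw sum-of-squares decomposition."""
    all_x = [x for g in groups for x in g]
    grand = sum(all_x) / len(all_x)
    ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_w = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df1 = len(groups) - 1
    df2 = len(all_x) - len(groups)
    return (ss_b / df1) / (ss_w / df2)


def kruskal_oracle(groups):
    """Kruskal-Wallis H with mid-ranks and tie correction."""
    pooled = sorted((x, gi) for gi, g in enumerate(groups) for x in g)
    n = len(pooled)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for t in range(i, j):
            ranks[t] = mid
        i = j
    rank_sums = [0.0] * len(groups)
    counts = [0] * len(groups)
    for idx, (_, gi) in enumerate(pooled):
        rank_sums[gi] += ranks[idx]
        counts[gi] += 1
    h = 12.0 / (n * (n + 1)) * sum(
        rs ** 2 / c for rs, c in zip(rank_sums, counts)) - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        ties += t ** 3 - t
        i = j
    correction = 1.0 - ties / (n ** 3 - n)
    return h / correction if correction > 0 else 0.0


def logistic_loglik(y, X, beta):
    eta = X @ beta
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def glm_grid_oracle(y, X, span=8.0, rounds=6, grid=21):
    """Coarse-to-fine grid maximisation of the logistic likelihood."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    p = X.shape[1]
    center = np.zeros(p)
    width = span
    best = None
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, grid) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        betas = np.column_stack([m.ravel() for m in mesh])
        lls = np.array([logistic_loglik(y, X, b) for b in betas])
        i = int(np.argmax(lls))
        best = lls[i]
        center = betas[i]
        width /= grid / 4.0
    return best, center


def hull_area_oracle(points):
    """Convex hull area by Andrew's monotone chain + shoelace."""
    pts = sorted(set(map(tuple, np.asarray(points, float))))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def _haversine_m(lon1, lat1, lon2, lat2):
    r = 6371.0088e3
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def clusters_oracle(lons, lats, radius_m=200.0, min_fixes=3):
    """Exhaustive forward scan of the greedy residency-cluster rule.

    From each start index, extend while each next fix lies within
    ``radius_m`` of the running centroid; emit maximal disjoint runs in
    time order, keeping runs of at least ``min_fixes``. Returns a list
    of (start_index, end_index) inclusive.
    """
    n = len(lons)
    out = []
    i = 0
    while i < n:
        sum_lon, sum_lat, cnt = lons[i], lats[i], 1
        j = i + 1
        while j < n:
            d = _haversine_m(sum_lon / cnt, sum_lat / cnt, lons[j], lats[j])
            if d > radius_m:
                break
            sum_lon += lons[j]
            sum_lat += lats[j]
            cnt += 1
            j += 1
        if cnt >= min_fixes:
            out.append((i, j - 1))
        i = j
    return out
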