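"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by the most literal route available
(explicit 2x2 matrix inverses, exhaustive path enumeration, direct pair
counting, stepwise simulation) and stays independent of the implementation
paths it is used to check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def mahalanobis_bruteforce(point, mean, cov) -> float:
    """Explicit adjugate 2x2 inverse, no linear-algebra library calls."""
    a, b = cov[0][0], cov[0][1]
    c, d = cov[1][0], cov[1][1]
    det = a * d - b * c
    inv = [[d / det, -b / det], [-c / det, a / det]]
    dx = point[0] - mean[0]
    dy = point[1] - mean[1]
    q = (dx * (inv[0][0] * dx + inv[0][1] * dy)
         + dy * (inv[1][0] * dx + inv[1][1] * dy))
    return q ** 0.5


def edge_weight_bruteforce(point, means, covs) -> float:
    """Minimum over components of the explicit Mahalanobis distance."""
    return min(mahalanobis_bruteforce(point, m, c) for m, c in zip(means, covs))


def all_pairs_shortest_paths(weights: np.ndarray):
    """All shortest paths by full simple-path enumeration (tiny graphs only).

    Returns {(s, t): (length, [paths])} for s < t, each path a node tuple.
    """
    n = weights.shape[0]
    out = {}
    for s, t in combinations(range(n), 2):
        best, paths = np.inf, []
        others = [v for v in range(n) if v not in (s, t)]
        for r in range(len(others) + 1):
            for mid in permutations(others, r):
                path = (s, *mid, t)
                length = sum(weights[path[i], path[i + 1]]
                             for i in range(len(path) - 1))
                if length < best - 1e-12:
                    best, paths = length, [path]
                elif abs(length - best) <= 1e-12:
                    paths.append(path)
        out[(s, t)] = (best, paths)
    return out


def betweenness_bruteforce(weights: np.ndarray) -> np.ndarray:
    """Pair-normalised betweenness from exhaustive path enumeration."""
    n = weights.shape[0]
    score = np.zeros(n)
    for (s, t), (_, paths) in all_pairs_shortest_paths(weights).items():
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            score[v] += through / sigma
    return score / ((n - 1) * (n - 2) / 2)


def eccentricity_bruteforce(weights: np.ndarray) -> np.ndarray:
    """Floyd-Warshall with explicit loops."""
    n = weights.shape[0]
    dist = weights.astype(float).copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = dist[i, k] + dist[k, j]
                if via < dist[i, j]:
                    dist[i, j] = via
    np.fill_diagonal(dist, 0.0)
    return dist.max(axis=1)


def auc_by_pair_counting(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC as the fraction of positive-negative pairs ranked correctly."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(group1, group2):
        return sum((a > b) + 0.5 * (a == b) for a in group1 for b in group2)

    observed = u_stat(x, y)
    n2 = len(y)
    mid = n1 * n2 / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = u_stat(g1, g2)
        total += 1
        if abs(u - mid) >= abs(observed - mid) - 1e-12:
            count += 1
    return count / total


def return_time_sds(transition: np.ndarray, steps: int, seed: int) -> np.ndarray:
    """Empirical SD of return times from a long simulated random walk."""
    rng = np.random.default_rng(seed)
    n = transition.shape[0]
    cum = np.cumsum(transition, axis=1)
    visits: list[list[int]] = [[] for _ in range(n)]
    state = 0
    draws = rng.random(steps)
    for t in range(steps):
        state = int(np.searchsorted(cum[state], draws[t]))
        visits[state].append(t)
    sds = np.full(n, np.nan)
    for v in range(n):
        times = np.diff(visits[v])
        if times.size > 1:
            sds[v] = times.std(ddof=0)
    return sds
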