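"""Brute-force reference implementations used only by the test suite.

Everything here is written for clarity, not speed: explicit loops over
nodes, neighbour pairs and hypergeometric terms, so each function is an
independent check on the vectorized library code.
"""

import math
from fractions import Fraction

import numpy as np


def clustering_binary(adj):
    """Exhaustive ordered-neighbour-pair enumeration of C(i)."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        closed = 0
        for j in nbrs:
            for q in nbrs:
                if q != j and adj[j, q]:
                    closed += 1
        out[i] = closed / (k * (k - 1))
    return out


def clustering_onnela(adj, weights):
    """Exhaustive triangle-intensity sum with |w_ij w_iq w_jq|^(1/3)."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j in nbrs:
            for q in nbrs:
                if q != j and adj[j, q]:
                    total += abs(weights[i, j] * weights[i, q] * weights[j, q]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def degree_assortativity(adj):
    """Pearson correlation over the explicit list of ordered endpoint-degree pairs."""
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def diameter_hops(adj):
    """All-pairs BFS on the largest connected component."""
    n = adj.shape[0]
    nbrs = [set(np.nonzero(adj[i])[0]) for i in range(n)]

    def bfs(start):
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    components = []
    seen = set()
    for i in range(n):
        if i not in seen:
            comp = set(bfs(i))
            seen |= comp
            components.append(comp)
    largest = max(components, key=len)
    best = 0
    for i in largest:
        best = max(best, max(bfs(i).values()))
    return best, len(largest), len(components) == 1


def size_factors(counts):
    """Median-of-ratios on an integer matrix, one literal step at a time."""
    counts = np.asarray(counts, float)
    n_genes, n_samples = counts.shape
    geomeans = []
    for g in range(n_genes):
        row = counts[g]
        if (row > 0).all():
            geomeans.append((g, math.exp(sum(math.log(v) for v in row) / n_samples)))
    factors = []
    for j in range(n_samples):
        ratios = sorted(counts[g, j] / gm for g, gm in geomeans)
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else (ratios[m // 2 - 1] + ratios[m // 2]) / 2
        factors.append(med)
    return np.array(factors)


def bh_adjust(pvalues):
    """Literal step-up rule: sort, scale by m/rank, enforce monotone, cap at 1."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return np.array(adjusted)


# exact Pascal triangle, precomputed for the exhaustive small-table sweep
_MAX_N = 61
_COMB = [[math.comb(n, k) for k in range(_MAX_N)] for n in range(_MAX_N)]


def _comb(n, k):
    if k < 0 or k > n:
        return 0
    return _COMB[n][k] if n < _MAX_N else math.comb(n, k)


def hypergeom_tail(k, K, n, N):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exact integer summation."""
    num = 0
    lo = max(k, 0, n + K - N)
    hi = min(n, K)
    for x in range(lo, hi + 1):
        num += _comb(K, x) * _comb(N - K, n - x)
    return float(Fraction(num, _comb(N, n)))


def hypergeom_pmf_total(K, n, N):
    """Self-check: the pmf over all reachable x sums to exactly 1."""
    total = Fraction(0)
    for x in range(max(0, n + K - N), min(n, K) + 1):
        total += Fraction(_comb(K, x) * _comb(N - K, n - x), _comb(N, n))
    return total


def pearson(u, v):
    """Covariance-formula Pearson correlation for two vectors."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    du, dv = u - u.mean(), v - v.mean()
    return float((du * dv).sum() / math.sqrt((du**2).sum() * (dv**2).sum()))


def random_signed_graph(rng, n_max=30, tau=0.1):
    """A random signed weighted graph: adjacency + correlation-like weights.

    Edge magnitudes are drawn in [0.2, 1] so that, with ``tau`` = 0.1,
    the thresholded view of the weight matrix reproduces exactly the
    planted adjacency (absent pairs have weight 0 < tau).
    """
    n = int(rng.integers(4, n_max + 1))
    density = float(rng.uniform(0.1, 0.9))
    upper = rng.random((n, n)) < density
    adj = np.triu(upper, 1)
    adj = adj | adj.T
    mag = rng.uniform(0.2, 1.0, size=(n, n))
    sign = np.where(rng.random((n, n)) < 0.5, -1.0, 1.0)
    w = np.triu(mag * sign, 1)
    w = w + w.T
    weights = np.where(adj, w, 0.0)
    return adj, weights, tau
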