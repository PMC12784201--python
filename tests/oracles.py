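"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — direct formula evaluation,
exhaustive enumeration, Floyd–Warshall — and shares no code with the
package's metric implementations.
"""

from __future__ import annotations

from itertools import combinations, permutations

import networkx as nx
import numpy as np


def cv_degrees(g: nx.Graph) -> float:
    deg = np.array([d for _, d in g.degree()], dtype=float)
    return deg.std(ddof=1) / deg.mean()


def endpoint_pearson_assortativity(g: nx.Graph) -> float:
    """Pearson of degrees over edge endpoints, both orientations."""
    deg = dict(g.degree())
    xs, ys = [], []
    for u, v in g.edges():
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def triangle_clustering(g: nx.Graph) -> float:
    """Mean local clustering by exhaustive neighbour-pair enumeration."""
    coeffs = []
    for u in g.nodes:
        nbrs = list(g.neighbors(u))
        k = len(nbrs)
        if k < 2:
            coeffs.append(0.0)
            continue
        closed = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
        coeffs.append(closed / (k * (k - 1) / 2))
    return float(np.mean(coeffs))


def floyd_warshall_mean_distance(g: nx.Graph, weight: str | None = None) -> float:
    nodes = list(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for u, v, d in g.edges(data=True):
        length = 1.0 / d[weight] if weight else 1.0
        i, j = idx[u], idx[v]
        D[i, j] = D[j, i] = min(D[i, j], length)
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    iu = np.triu_indices(n, k=1)
    return float(D[iu].mean())


def newman_categorical_assortativity(g: nx.Graph, cats) -> float:
    """Newman's coefficient from the edge mixing matrix, by direct formula."""
    cats = np.asarray(cats)
    labels = sorted(set(int(c) for c in cats))
    k = len(labels)
    pos = {c: i for i, c in enumerate(labels)}
    e = np.zeros((k, k))
    for u, v in g.edges():
        i, j = pos[int(cats[u])], pos[int(cats[v])]
        e[i, j] += 1
        e[j, i] += 1
    e /= e.sum()
    a = e.sum(axis=1)
    tr = np.trace(e)
    s = float(a @ a)
    if s == 1.0:
        return float("nan")
    return float((tr - s) / (1.0 - s))


def endpoint_trait_pearson(g: nx.Graph, vals) -> float:
    vals = np.asarray(vals, float)
    xs, ys = [], []
    for u, v in g.edges():
        xs += [vals[u], vals[v]]
        ys += [vals[v], vals[u]]
    return float(np.corrcoef(xs, ys)[0, 1])


def bfs_eccentricity(g: nx.Graph, source) -> int:
    return max(nx.single_source_shortest_path_length(g, source).values())


def sequential_edge_set_probs(weights, m: int) -> dict[frozenset, float]:
    """Exact edge-set probabilities of m sequential proportional draws
    without replacement, by summation over all ordered sequences."""
    weights = list(map(float, weights))
    probs: dict[frozenset, float] = {}
    for seq in permutations(range(len(weights)), m):
        p, rem = 1.0, sum(weights)
        for e in seq:
            p *= weights[e] / rem
            rem -= weights[e]
        key = frozenset(seq)
        probs[key] = probs.get(key, 0.0) + p
    return probs


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """Rejection-sample a connected G(n, p) with a seeded generator."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() and nx.is_connected(g):
            return g
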