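"""Draw connected, optionally weighted networks from an attraction matrix.

The edge set is a weighted sample without replacement: ``m = round(n·d̄/2)``
unordered pairs are drawn one at a time, each with probability proportional
to its social attraction among the pairs still in the pool. Connectivity is
enforced by rejection — a draw whose graph has more than one component is
discarded and redrawn in full, which preserves the conditional edge-set
distribution (repairing a disconnected draw would not).

The sequential draw is realised with exponential race keys (the Gumbel
top-m / Efraimidis–Spirakis construction), which yields exactly the same
edge-set distribution as drawing pairs one by one and is O(n²) per attempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .preferences import AttractionMatrix
from .traits import Population

__all__ = [
    "SocialNetwork",
    "GenerationError",
    "draw_network",
    "edge_count",
    "write_edgelist_csv",
    "read_edgelist_csv",
    "write_graphml",
    "read_graphml",
]

DEFAULT_MAX_RETRIES = 100_000


class GenerationError(RuntimeError):
    """All retries produced disconnected draws; carries the rejection count."""

    def __init__(self, msg: str, rejections: int):
        super().__init__(msg)
        self.rejections = rejections


@dataclass
class SocialNetwork:
    """Undirected connected social network with optional edge weights.

    ``graph`` is a :class:`networkx.Graph` on nodes ``0..n-1``; weighted
    networks carry a positive ``weight`` attribute per edge, normalised so
    the mean edge weight is 1. ``population`` holds the traits the network
    was generated from; ``meta`` records the generation parameters and the
    number of connectivity rejections.
    """

    graph: nx.Graph
    population: Population | None = None
    weighted: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()], dtype=float)

    def weighted_degrees(self) -> np.ndarray:
        w = "weight" if self.weighted else None
        return np.array([d for _, d in self.graph.degree(weight=w)], dtype=float)


def edge_count(n: int, mean_degree: float) -> int:
    """Number of edges for a target mean degree; half-integers round up."""
    return int(np.floor(n * mean_degree / 2.0 + 0.5))


def _sample_edges(
    weights: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of m items sampled without replacement, ∝ weights sequentially."""
    # smallest exponential arrival times <=> sequential proportional draws
    keys = rng.exponential(size=weights.shape[0]) / weights
    return np.argpartition(keys, m)[:m]


def draw_network(
    A: AttractionMatrix,
    mean_degree: float,
    weighted: bool = True,
    rng: np.random.Generator | None = None,
    max_retries: int = DEFAULT_MAX_RETRIES,
    population: Population | None = None,
) -> SocialNetwork:
    """Draw a connected network with ``m = round(n·d̄/2)`` edges from ``A``.

    Each of the m edges is drawn with probability proportional to its
    attraction among the remaining pairs; in weighted mode the edge weight
    is the attraction rescaled to mean 1 over the drawn edges. Disconnected
    draws are rejected and redrawn (traits and attraction fixed) up to
    ``max_retries`` times.

    Raises
    ------
    GenerationError
        If every retry produced a disconnected graph.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = A.n
    m = edge_count(n, mean_degree)
    n_pairs = n * (n - 1) // 2
    if m < n - 1:
        raise ValueError(
            f"mean degree {mean_degree} gives {m} edges; at least {n - 1} "
            f"needed for a connected graph on {n} nodes"
        )
    if m > n_pairs:
        raise ValueError(f"{m} edges requested but only {n_pairs} pairs exist")
    if max_retries < 1:
        raise ValueError("max_retries must be >= 1")

    iu, ju = np.triu_indices(n, k=1)
    pair_attraction = A.values[iu, ju]
    if np.any(pair_attraction <= 0):
        raise ValueError("attraction matrix has non-positive off-diagonal entries")

    rejections = 0
    for _ in range(max_retries):
        chosen = _sample_edges(pair_attraction, m, rng)
        ei, ej = iu[chosen], ju[chosen]
        g = nx.Graph()
        g.add_nodes_from(range(n))
        if weighted:
            w = pair_attraction[chosen]
            w = w / w.mean()
            g.add_weighted_edges_from(zip(ei.tolist(), ej.tolist(), w.tolist()))
        else:
            g.add_edges_from(zip(ei.tolist(), ej.tolist()))
        if nx.is_connected(g):
            net = SocialNetwork(
                graph=g,
                population=population,
                weighted=weighted,
                meta={
                    "mean_degree": mean_degree,
                    "m": m,
                    "rejections": rejections,
                    "weighted": weighted,
                },
            )
            return net
        rejections += 1
    raise GenerationError(
        f"no connected network in {max_retries} draws "
        f"(n={n}, m={m}); the attraction matrix may be too close to "
        "block-diagonal",
        rejections=rejections,
    )


# -- readers / writers ----------------------------------------------------


def write_edgelist_csv(net: SocialNetwork, path) -> None:
    """Edge list as ``source,target,weight`` CSV (weight 1 if unweighted)."""
    rows = [
        (u, v, d.get("weight", 1.0))
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )


def read_edgelist_csv(path, n: int | None = None, weighted: bool = True) -> SocialNetwork:
    df = pd.read_csv(path)
    g = nx.Graph()
    if n is not None:
        g.add_nodes_from(range(n))
    for u, v, w in df.itertuples(index=False):
        if weighted:
            g.add_edge(int(u), int(v), weight=float(w))
        else:
            g.add_edge(int(u), int(v))
    return SocialNetwork(graph=g, weighted=weighted)


def write_graphml(net: SocialNetwork, path) -> None:
    """GraphML with trait values attached as node attributes."""
    g = net.graph.copy()
    if net.population is not None:
        for name in net.population.traits:
            vals = net.population[name]
            nx.set_node_attributes(
                g, {i: vals[i].item() for i in range(net.population.n)}, name
            )
    nx.write_graphml(g, path)


def read_graphml(path, weighted: bool = True) -> SocialNetwork:
    g = nx.read_graphml(path, node_type=int)
    return SocialNetwork(graph=g, weighted=weighted)
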