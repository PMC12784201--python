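"""Global structure measures for generated social networks.

Six measures, averaged over network ensembles downstream:

* degree variation — coefficient of variation of the degree sequence;
* degree assortativity — Pearson correlation of degrees over edge endpoints;
* clustering — mean local clustering coefficient;
* mean distance — average shortest-path length over node pairs;
* popularity-trait–degree correlation — Pearson of trait value vs degree,
  the signature of a popularity preference;
* similarity-trait assortativity — the signature of a similarity
  preference (Newman's coefficient for categorical traits, endpoint
  Pearson for normal, circular-proximity contrast for circular).

Weighted variants of the first four use weighted degrees, Onnela-style
triangle intensities, and shortest paths with edge length ``1/weight``.

Degenerate cases (constant degrees, a single category, …) return ``nan``,
the tagged-undefined value; ensemble aggregation excludes them with a
count rather than coercing to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

from .netgen import SocialNetwork
from .preferences import _circular_distance
from .traits import CATEGORICAL, CIRCULAR

__all__ = [
    "MetricSet",
    "degree_variation",
    "degree_assortativity",
    "clustering",
    "mean_distance",
    "trait_degree_correlation",
    "trait_assortativity",
    "compute_metrics",
]


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, SocialNetwork) else net


def _degrees(g: nx.Graph, weight: str | None) -> np.ndarray:
    return np.array([d for _, d in g.degree(weight=weight)], dtype=float)


def _pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> float:
    """(Weighted) Pearson correlation; nan if either variable is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    mx, my = (w * x).sum() / sw, (w * y).sum() / sw
    vx = (w * (x - mx) ** 2).sum() / sw
    vy = (w * (y - my) ** 2).sum() / sw
    if vx <= 0 or vy <= 0:
        return float("nan")
    cov = (w * (x - mx) * (y - my)).sum() / sw
    return float(cov / np.sqrt(vx * vy))


def degree_variation(net, weight: str | None = None) -> float:
    """Coefficient of variation (sample sd / mean) of (weighted) degrees."""
    g = _as_graph(net)
    deg = _degrees(g, weight)
    mean = deg.mean()
    if mean == 0:
        return float("nan")
    sd = deg.std(ddof=1) if len(deg) > 1 else 0.0
    return float(sd / mean)


def degree_assortativity(net, weight: str | None = None) -> float:
    """Pearson correlation of (weighted) degrees across edge endpoints.

    Both orientations of each edge are included; the weighted variant
    weights endpoint pairs by edge weight. ``nan`` if endpoint degrees are
    constant (e.g. a complete or regular graph).
    """
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        return float("nan")
    deg = _degrees(g, weight)
    us, vs, ws = [], [], []
    for u, v, d in g.edges(data=True):
        ew = d.get(weight, 1.0) if weight else 1.0
        us.extend((u, v))
        vs.extend((v, u))
        ws.extend((ew, ew))
    return _pearson(deg[np.array(us)], deg[np.array(vs)], np.array(ws))


def clustering(net, weight: str | None = None) -> float:
    """Mean local clustering coefficient (degree-<2 nodes contribute 0).

    The weighted variant is the Onnela intensity coefficient: geometric
    mean of max-normalised triangle weights.
    """
    g = _as_graph(net)
    return float(nx.average_clustering(g, weight=weight, count_zeros=True))


def mean_distance(net, weight: str | None = None) -> float:
    """Average shortest-path length over unordered node pairs.

    The weighted variant travels edges at length ``1/weight``, so strong
    ties are short. Raises if the graph is disconnected.
    """
    g = _as_graph(net)
    if not nx.is_connected(g):
        raise ValueError("mean distance requires a connected graph")
    if weight is None:
        return float(nx.average_shortest_path_length(g))
    h = g.copy()
    for u, v, d in h.edges(data=True):
        d["_len"] = 1.0 / d[weight]
    return float(nx.average_shortest_path_length(h, weight="_len"))


def trait_degree_correlation(net, values) -> float:
    """Pearson correlation of trait values with unweighted degrees.

    The expected signature of a popularity preference: individuals with
    more popular trait values accumulate more links.
    """
    g = _as_graph(net)
    return _pearson(np.asarray(values, dtype=float), _degrees(g, None))


def trait_assortativity(
    net,
    values,
    kind: str = "numeric",
    circumference: float = 1.0,
) -> float:
    """Assortment of connected individuals by trait value.

    categorical
        Newman's discrete assortativity coefficient of the edge mixing
        matrix; 1 when edges never cross categories. ``nan`` with a single
        category present.
    numeric (normal traits)
        Pearson correlation of endpoint trait values over edges (both
        orientations).
    circular
        Mean over edges of the circular proximity ``1 - d/(C/2)``,
        standardised by the all-pairs proximity mean and sd (a
        Mantel-style contrast; 0 under no assortment, positive when
        neighbours are closer on the circle than random pairs).
    """
    g = _as_graph(net)
    values = np.asarray(values)
    if g.number_of_edges() == 0:
        return float("nan")
    if kind in (CATEGORICAL, "categorical"):
        if len(np.unique(values)) < 2:
            return float("nan")
        h = g.copy()
        nx.set_node_attributes(
            h, {i: int(values[i]) for i in h.nodes}, "_cat"
        )
        return float(nx.attribute_assortativity_coefficient(h, "_cat"))
    if kind in (CIRCULAR, "circular"):
        vals = values.astype(float)
        n = len(vals)
        iu, ju = np.triu_indices(n, k=1)
        prox_all = 1.0 - _circular_distance(vals[iu], vals[ju], circumference) / (
            circumference / 2.0
        )
        sd = prox_all.std(ddof=0)
        if sd == 0:
            return float("nan")
        edges = np.array(g.edges())
        prox_edges = 1.0 - _circular_distance(
            vals[edges[:, 0]], vals[edges[:, 1]], circumference
        ) / (circumference / 2.0)
        return float((prox_edges.mean() - prox_all.mean()) / sd)
    # numeric
    vals = values.astype(float)
    us, vs = [], []
    for u, v in g.edges():
        us.extend((u, v))
        vs.extend((v, u))
    return _pearson(vals[np.array(us)], vals[np.array(vs)])


@dataclass
class MetricSet:
    """The six global measures plus weighted twins of the first four."""

    degree_variation: float
    degree_assortativity: float
    clustering: float
    mean_distance: float
    pop_trait_degree_corr: float
    sim_trait_assortativity: float
    w_degree_variation: float = float("nan")
    w_degree_assortativity: float = float("nan")
    w_clustering: float = float("nan")
    w_mean_distance: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_metrics(
    net: SocialNetwork,
    popularity_trait: str | None = None,
    similarity_trait: str | None = None,
    weighted: bool | None = None,
) -> MetricSet:
    """All measures for one network.

    Trait-pattern statistics are computed for the named traits of the
    network's population (``nan`` if unnamed). Weighted variants are
    computed when the network carries weights unless disabled.
    """
    g = net.graph
    pop = net.population
    if weighted is None:
        weighted = net.weighted

    def _trait(name: str | None):
        if name is None or pop is None or name not in pop:
            return None, None
        return pop[name], pop.traits[name]

    pvals, _ = _trait(popularity_trait)
    svals, sspec = _trait(similarity_trait)

    ptdc = trait_degree_correlation(g, pvals) if pvals is not None else float("nan")
    if svals is not None:
        assert sspec is not None
        sta = trait_assortativity(
            g, svals, kind=sspec.kind, circumference=sspec.circumference
        )
    else:
        sta = float("nan")

    out = MetricSet(
        degree_variation=degree_variation(g),
        degree_assortativity=degree_assortativity(g),
        clustering=clustering(g),
        mean_distance=mean_distance(g),
        pop_trait_degree_corr=ptdc,
        sim_trait_assortativity=sta,
    )
    if weighted:
        out.w_degree_variation = degree_variation(g, weight="weight")
        out.w_degree_assortativity = degree_assortativity(g, weight="weight")
        out.w_clustering = clustering(g, weight="weight")
        out.w_mean_distance = mean_distance(g, weight="weight")
    return out
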