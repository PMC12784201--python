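"""Sequential node-removal experiments and component break time.

Networks lose nodes one at a time until two remain, mimicking the death or
dispersal of individuals. Four removal orders are studied: random
(position-independent loss), highest degree first (loss of the most
connected), lowest degree first (loss of the most isolated), and highest
betweenness first (loss of social bridges). Robustness is the *component
break time*: the number of removals before the remaining graph first
splits into more than one component (isolated nodes count), capped at
``n - 2`` if it never breaks.

Rankings are computed once on the intact network by default, which keeps
runs cheap and exactly reproducible; ``dynamic=True`` recomputes the
criterion on the remaining graph before each removal. Ties are broken
uniformly at random with the supplied generator, since deterministic
id-order tie-breaking would bias removal against trait categories that
correlate with degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netgen import SocialNetwork

__all__ = [
    "RemovalStrategy",
    "RobustnessResult",
    "removal_order",
    "component_break_time",
    "STRATEGIES",
]

RANDOM = "random"
DEGREE_HIGH = "degree_high_first"
DEGREE_LOW = "degree_low_first"
BETWEENNESS_HIGH = "betweenness_high_first"
STRATEGIES = (RANDOM, DEGREE_HIGH, DEGREE_LOW, BETWEENNESS_HIGH)


@dataclass(frozen=True)
class RemovalStrategy:
    """Removal order plus weighting/recomputation flags.

    ``use_weights`` ranks by weighted degree (or betweenness along paths of
    length ``1/weight``); ``dynamic`` recomputes the ranking on the
    remaining graph after every removal.
    """

    order: str = RANDOM
    use_weights: bool = False
    dynamic: bool = False

    def __post_init__(self) -> None:
        if self.order not in STRATEGIES:
            raise ValueError(
                f"unknown removal strategy {self.order!r}; expected one of {STRATEGIES}"
            )

    @property
    def label(self) -> str:
        return f"{self.order}{'_w' if self.use_weights else ''}"


@dataclass
class RobustnessResult:
    """Break time and the largest-component trajectory of one removal run."""

    break_time: int
    lcc_trajectory: list[int]
    order: list[int]


def _criterion(g: nx.Graph, strategy: RemovalStrategy) -> dict:
    weight = "weight" if strategy.use_weights else None
    if strategy.order in (DEGREE_HIGH, DEGREE_LOW):
        return dict(g.degree(weight=weight))
    # betweenness; strong ties are short paths
    if weight is None:
        return nx.betweenness_centrality(g, normalized=False)
    h = g.copy()
    for _, _, d in h.edges(data=True):
        d["_len"] = 1.0 / d["weight"]
    return nx.betweenness_centrality(h, normalized=False, weight="_len")


def _ranked_pick(scores: dict, high_first: bool, rng: np.random.Generator):
    nodes = list(scores)
    vals = np.array([scores[u] for u in nodes], dtype=float)
    if not high_first:
        vals = -vals
    best = np.flatnonzero(vals == vals.max())
    return nodes[best[rng.integers(len(best))]]


def removal_order(
    net: SocialNetwork | nx.Graph,
    strategy: RemovalStrategy,
    rng: np.random.Generator,
) -> list[int]:
    """The first ``n - 2`` nodes to remove under the strategy.

    Ties are broken uniformly at random. In dynamic mode the ranking
    criterion is recomputed on the remaining graph before each pick.
    """
    g = (net.graph if isinstance(net, SocialNetwork) else net)
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("removal experiments require at least 3 nodes")
    k = n - 2
    if strategy.order == RANDOM:
        return [int(u) for u in rng.permutation(list(g.nodes))[:k]]
    high_first = strategy.order != DEGREE_LOW
    if strategy.dynamic:
        h = g.copy()
        order = []
        for _ in range(k):
            pick = _ranked_pick(_criterion(h, strategy), high_first, rng)
            order.append(int(pick))
            h.remove_node(pick)
        return order
    scores = _criterion(g, strategy)
    nodes = list(scores)
    vals = np.array([scores[u] for u in nodes], dtype=float)
    if not high_first:
        vals = -vals
    # random tie-break: sort on (-score, uniform jitter)
    jitter = rng.random(len(nodes))
    idx = np.lexsort((jitter, -vals))
    return [int(nodes[i]) for i in idx[:k]]


def component_break_time(
    net: SocialNetwork | nx.Graph, order: list[int]
) -> RobustnessResult:
    """Remove nodes in ``order`` and report when the network fragments.

    ``break_time`` is the smallest number of removals after which the graph
    induced on the remaining nodes has more than one component (isolated
    nodes count as components); ``n - 2`` if it survives to the end.
    """
    g = (net.graph if isinstance(net, SocialNetwork) else net).copy()
    n = g.number_of_nodes()
    if not nx.is_connected(g):
        raise ValueError("component_break_time requires a connected start graph")
    if len(order) != n - 2:
        raise ValueError(f"order must list n-2={n - 2} nodes, got {len(order)}")
    if len(set(order)) != len(order) or not set(order) <= set(g.nodes):
        raise ValueError("order contains duplicates or unknown nodes")

    break_time = n - 2
    trajectory: list[int] = []
    broken = False
    for r, node in enumerate(order, start=1):
        g.remove_node(node)
        comps = list(nx.connected_components(g))
        trajectory.append(max(len(c) for c in comps))
        if not broken and len(comps) > 1:
            break_time = r
            broken = True
    return RobustnessResult(
        break_time=break_time, lcc_trajectory=trajectory, order=list(order)
    )
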