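"""The four topological parameters: degree, ASPL, clustering, betweenness.

All metrics are unweighted and computed on the undirected simple graph.
Shortest paths are hop counts from breadth-first search. Betweenness uses
Brandes' single-source accumulation; its output is defined over unordered
node pairs with the endpoints excluded, and is normalized by
(N-1)(N-2)/2 by default so values lie in [0, 1].

Everything here is deterministic: nodes are visited in lexicographic
order, so repeated runs produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from .graphio import GeneSet, Interactome

logger = logging.getLogger(__name__)

PARAMETERS = ("degree", "aspl", "cc", "bc")


@dataclass(frozen=True)
class NodeMetrics:
    """Per-gene record of the four topological parameters.

    degree
        Number of incident edges.
    aspl
        Mean shortest-path distance (in edges) to every other reachable
        node.
    cc
        Local clustering coefficient 2n / (k(k-1)) with n the number of
        edges among the node's neighbors; 0 by convention when degree < 2.
    bc
        Betweenness centrality, normalized to [0, 1].
    """

    gene: str
    degree: int
    aspl: float
    cc: float
    bc: float

    def value(self, parameter: str) -> float:
        if parameter not in PARAMETERS:
            raise KeyError(parameter)
        return getattr(self, parameter)


def bfs_distances(net: Interactome, source: str) -> dict[str, int]:
    """Hop distances from ``source`` to every reachable node.

    The distance from a node to itself is 0. Unreachable nodes are absent
    from the returned mapping.
    """
    if source not in net:
        raise ValueError(f"source {source!r} not in network")
    adj = net.adj
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for w in adj[u]:
            if w not in dist:
                dist[w] = du + 1
                queue.append(w)
    return dist


def node_aspl(net: Interactome, v: str) -> float:
    """Mean shortest-path distance from ``v`` to all reachable nodes.

    Unreachable nodes are excluded from the average; an isolated node has
    no reachable partner and raises ``ValueError``.
    """
    dist = bfs_distances(net, v)
    reachable = len(dist) - 1
    if reachable == 0:
        raise ValueError(f"node {v!r} has no reachable partner")
    return sum(dist.values()) / reachable


def network_apl(net: Interactome, normalization: str = "conventional") -> float:
    """Network-level average shortest path length.

    ``conventional`` averages over the N(N-1)/2 unordered distinct pairs.
    ``inclusive`` divides the same distance total by N(N+1)/2, i.e. the
    self-pairs (distance 0) inflate the denominator — a variant that
    appears in the literature. Both are exposed because published
    per-gene values cannot adjudicate between them.
    """
    if normalization not in ("conventional", "inclusive"):
        raise ValueError(f"unknown normalization {normalization!r}")
    n = net.n_nodes
    if n < 2:
        raise ValueError("network_apl requires at least 2 nodes")
    if not net.is_connected():
        raise ValueError("network_apl requires a connected graph")
    total_ordered = 0
    for v in sorted(net.nodes):
        total_ordered += sum(bfs_distances(net, v).values())
    # total over unordered pairs = total_ordered / 2
    if normalization == "inclusive":
        return total_ordered / (n * (n + 1))
    return total_ordered / (n * (n - 1))


def clustering_coefficient(net: Interactome, v: str) -> float:
    """Local clustering coefficient 2n / (k(k-1)).

    n counts edges whose both endpoints neighbor ``v``; it is obtained as
    half the number of symmetric adjacency incidences among the neighbors.
    Nodes of degree < 2 have no neighbor pair and get 0.
    """
    if v not in net:
        raise ValueError(f"node {v!r} not in network")
    nbrs = net.neighbors(v)
    k = len(nbrs)
    if k < 2:
        return 0.0
    adj = net.adj
    incidences = sum(len(nbrs & set(adj[u])) for u in nbrs)
    n_edges = incidences / 2
    return 2.0 * n_edges / (k * (k - 1))


def betweenness_centrality(
    net: Interactome, normalized: bool = True
) -> dict[str, float]:
    """Betweenness centrality of every node (Brandes accumulation).

    For node v, sums over unordered pairs {i, j} with i != v != j the
    fraction of shortest i-j paths that pass through v. Unreachable pairs
    contribute 0. With ``normalized`` the sum is divided by (N-1)(N-2)/2,
    the number of pairs a node could lie between, giving values in [0, 1].
    """
    nodes = sorted(net.nodes)
    adj = net.adj
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest paths with path counting
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(nodes, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for w in adj[u]:
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    pred[w].append(u)
        # back-propagation of pair dependencies
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for u in pred[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    for v in bc:
        bc[v] /= 2.0
    if normalized:
        n = len(nodes)
        scale = (n - 1) * (n - 2) / 2.0
        if scale > 0:
            for v in bc:
                bc[v] /= scale
    return bc


def compute_all_metrics(
    net: Interactome,
    targets: Optional[Union[GeneSet, Sequence[str]]] = None,
    bc_cache: Optional[Mapping[str, float]] = None,
) -> list[NodeMetrics]:
    """Assemble a :class:`NodeMetrics` record per target gene.

    ``targets=None`` computes metrics for every node (lexicographic
    order); otherwise target order is preserved. Targets absent from the
    network are skipped with a warning; if none is present, raises
    ``ValueError``. Betweenness is computed once for the whole graph and
    looked up (pass ``bc_cache`` to reuse it across calls).
    """
    if targets is None:
        order: Iterable[str] = sorted(net.nodes)
    else:
        wanted = list(targets)
        absent = [g for g in wanted if g not in net]
        if absent:
            logger.warning(
                "%d target gene(s) absent from network (e.g. %s)",
                len(absent),
                absent[:5],
            )
        order = [g for g in wanted if g in net]
        if not order:
            raise ValueError("no target gene is present in the network")
    bc = bc_cache if bc_cache is not None else betweenness_centrality(net)
    return [
        NodeMetrics(
            gene=v,
            degree=net.degree(v),
            aspl=node_aspl(net, v),
            cc=clustering_coefficient(net, v),
            bc=bc[v],
        )
        for v in order
    ]
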