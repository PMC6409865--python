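"""Synthetic interactomes with a planted disease-gene signature.

Real interactomes are heavy-tailed (a few hub genes, many peripheral
ones), highly clustered locally, and small-world. The generator grows
such graphs by preferential attachment with a triadic-closure step: each
new gene links to ``edges_per_new_node`` existing genes, choosing either
proportionally to current degree or, with probability
``triangle_probability``, a neighbor of the previously chosen target
(closing a triangle). Triadic closure keeps the degree distribution
heavy-tailed while raising local clustering to interactome-like levels;
setting ``triangle_probability=0`` recovers plain preferential attachment.

``plant_disease_genes`` builds several independent communities and adds
connector genes that each link to a few *low-degree* members of every
community. Connectors therefore bridge the communities: they acquire high
betweenness (all inter-community shortest paths pass through them), low
average shortest path length (they sit between everything) and near-zero
clustering (their neighbors live in different communities), while their
degree stays unremarkable — low-degree attachment is deliberate, so the
planted signature dissociates betweenness prominence from degree
prominence.

All randomness flows through one seeded generator per call; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphio import GeneSet, Interactome
from .metrics import NodeMetrics


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-interactome generator.

    n_nodes: genes per generated scale-free graph (per community when
    planting).
    edges_per_new_node: attachment count m of the growth process.
    triangle_probability: chance that an attachment closes a triangle
    instead of following preferential attachment.
    n_communities / planted_count / connector_links_per_community: layout
    of the planted construction.
    """

    n_nodes: int = 200
    edges_per_new_node: int = 3
    triangle_probability: float = 0.6
    n_communities: int = 2
    planted_count: int = 22
    connector_links_per_community: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.edges_per_new_node < 1:
            raise ValueError("edges_per_new_node must be >= 1")
        if self.n_nodes <= self.edges_per_new_node:
            raise ValueError("n_nodes must exceed edges_per_new_node")
        if not 0.0 <= self.triangle_probability <= 1.0:
            raise ValueError("triangle_probability must be in [0, 1]")
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if self.planted_count < 0:
            raise ValueError("planted_count must be >= 0")
        if self.planted_count >= self.n_nodes:
            raise ValueError("planted_count must be < n_nodes")
        if self.connector_links_per_community < 1:
            raise ValueError("connector_links_per_community must be >= 1")


def _grow(
    n: int, m: int, p_triangle: float, rng: np.random.Generator, prefix: str
) -> dict[str, set[str]]:
    """Clique-seeded preferential attachment with triadic closure.

    Starts from a clique on the first m nodes; each subsequent node
    attaches to m distinct existing nodes. Edge count is
    C(m,2) + m*(n-m); the graph is connected and simple by construction.
    """
    labels = [f"{prefix}{i:04d}" for i in range(n)]
    adj: dict[str, set[str]] = {v: set() for v in labels}
    ends: list[str] = []  # one entry per half-edge: degree-proportional draws

    def add_edge(a: str, b: str) -> None:
        adj[a].add(b)
        adj[b].add(a)
        ends.append(a)
        ends.append(b)

    for i in range(m):
        for j in range(i + 1, m):
            add_edge(labels[i], labels[j])
    for i in range(m, n):
        v = labels[i]
        chosen: list[str] = []
        while len(chosen) < m:
            target = None
            if chosen and rng.random() < p_triangle:
                candidates = sorted(adj[chosen[-1]] - set(chosen) - {v})
                if candidates:
                    target = candidates[rng.integers(len(candidates))]
            if target is None:
                while True:
                    target = ends[rng.integers(len(ends))]
                    if target != v and target not in chosen:
                        break
            chosen.append(target)
        for t in chosen:
            add_edge(v, t)
    return adj


def _to_interactome(adj: dict[str, set[str]]) -> Interactome:
    g = nx.Graph()
    g.add_nodes_from(adj)
    g.add_edges_from((a, b) for a, nbrs in adj.items() for b in nbrs if a < b)
    return Interactome(g)


def generate_scale_free(spec: GeneratorSpec) -> Interactome:
    """One connected scale-free interactome, reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    adj = _grow(
        spec.n_nodes,
        spec.edges_per_new_node,
        spec.triangle_probability,
        rng,
        prefix="G",
    )
    return Interactome.from_edges(
        (a, b) for a, nbrs in adj.items() for b in nbrs if a < b
    )


def plant_disease_genes(spec: GeneratorSpec) -> tuple[Interactome, GeneSet]:
    """Communities bridged by connector genes with the disease signature.

    Builds ``n_communities`` independent scale-free communities of
    ``n_nodes`` genes each, then adds ``planted_count`` connector genes,
    each linked to ``connector_links_per_community`` distinct low-degree
    members of every community (low-degree = current degree at most the
    attachment parameter m, widened to the lowest-degree nodes if that
    pool runs short). Connector degree is exactly
    n_communities * connector_links_per_community. With at least one
    connector the merged graph is connected; with none it falls apart
    into its communities and the planted set is empty.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.edges_per_new_node
    adj: dict[str, set[str]] = {}
    communities: list[list[str]] = []
    for c in range(spec.n_communities):
        part = _grow(
            spec.n_nodes, m, spec.triangle_probability, rng, prefix=f"C{c + 1}_G"
        )
        adj.update(part)
        communities.append(sorted(part))
    connectors = [f"DG{k + 1:02d}" for k in range(spec.planted_count)]
    links = spec.connector_links_per_community
    for v in connectors:
        adj[v] = set()
        for members in communities:
            pool = sorted(u for u in members if len(adj[u]) <= m)
            if len(pool) < links:
                pool = sorted(members, key=lambda u: (len(adj[u]), u))[
                    : max(links, len(pool))
                ]
            picks = rng.choice(pool, size=links, replace=False)
            for u in picks:
                adj[v].add(u)
                adj[u].add(v)
    return _to_interactome(adj), GeneSet(name="planted", members=tuple(connectors))


#: Topology of the ten most intensively studied human disease genes in an
#: integrated 7018-gene functional-interaction network, as published.
#: Columns: gene, degree, average shortest path length, clustering
#: coefficient, betweenness centrality (decimal form).
_TOP_TEN_METRICS: tuple[tuple[str, int, float, float, float], ...] = (
    ("TP53", 178, 2.57, 0.39, 0.117),
    ("TNF", 137, 2.12, 0.47, 0.0164),
    ("EGFR", 228, 2.38, 0.42, 0.0306),
    ("VEGFA", 85, 2.23, 0.45, 0.00805),
    ("APOE", 68, 2.50, 0.40, 0.0103),
    ("IL6", 100, 2.18, 0.46, 0.0145),
    ("TGFB1", 96, 2.46, 0.41, 0.0359),
    ("MTHFR", 102, 2.45, 0.41, 0.0663),
    ("ESR1", 122, 2.55, 0.39, 0.0641),
    ("AKT1", 141, 1.99, 0.50, 0.123),
)


def table2_fixture() -> list[NodeMetrics]:
    """Published per-gene topology of the ten most-studied disease genes.

    These values were measured on an unpublished integrated interactome
    and are packaged as reference data (e.g. for the rank-correlation
    analysis); they are never recomputed here.
    """
    return [
        NodeMetrics(gene=g, degree=d, aspl=a, cc=c, bc=b)
        for g, d, a, c, b in _TOP_TEN_METRICS
    ]


def toy_graphs() -> dict[str, Interactome]:
    """Tiny named graphs with closed-form metrics, for tests and examples.

    path4: a-b-c-d. Endpoint ASPL 2.0, inner 4/3; normalized BC of an
        inner node 2/3; conventional network APL 5/3.
    star4: hub plus 4 leaves. Hub ASPL 1, CC 0, normalized BC 1.
    k4: complete graph; ASPL 1, CC 1, BC 0 everywhere.
    triangle_pendant: triangle a,b,c with pendant d on a; CC(a) = 1/3.
    barbell: two triangles joined by the bridge c-d; the bridge endpoints
        carry the two largest betweenness values.
    """
    return {
        "path4": Interactome.from_edges([("a", "b"), ("b", "c"), ("c", "d")]),
        "star4": Interactome.from_edges(
            [("hub", leaf) for leaf in ("a", "b", "c", "d")]
        ),
        "k4": Interactome.from_edges(
            [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        ),
        "triangle_pendant": Interactome.from_edges(
            [("a", "b"), ("b", "c"), ("c", "a"), ("a", "d")]
        ),
        "barbell": Interactome.from_edges(
            [
                ("a", "b"),
                ("b", "c"),
                ("c", "a"),
                ("d", "e"),
                ("e", "f"),
                ("f", "d"),
                ("c", "d"),
            ]
        ),
    }
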