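"""Reading, writing and querying interactomes and gene sets.

An interactome is an undirected simple graph over gene symbols. Symbols are
case-sensitive and taken verbatim; no identifier mapping is performed. Edge
lists are two-column TSV (extra columns such as confidence scores are
ignored); gene sets are plain text, one symbol per line.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

Source = Union[str, Path, TextIO]

METRICS_COLUMNS = ("gene", "degree", "aspl", "cc", "bc")


class Interactome:
    """Undirected simple graph of gene symbols.

    Thin wrapper over :class:`networkx.Graph` that enforces the domain
    invariants (no self-loops, non-empty string labels) and exposes the
    queries the analysis needs. The adjacency structure is available through
    :attr:`adj` for the shortest-path and centrality algorithms.
    """

    def __init__(self, graph: nx.Graph):
        for v in graph.nodes:
            if not isinstance(v, str) or not v:
                raise ValueError(f"gene symbols must be non-empty strings, got {v!r}")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")
        self._g = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Interactome":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def adj(self):
        """Read-only adjacency mapping gene -> neighbor view."""
        return self._g.adj

    def neighbors(self, v: str) -> set[str]:
        return set(self._g.adj[v])

    def degree(self, v: str) -> int:
        return self._g.degree(v)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (min, max) symbol pairs, deterministic order."""
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    def __contains__(self, v: str) -> bool:
        return v in self._g

    def __len__(self) -> int:
        return self.n_nodes

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._g)

    def subgraph(self, nodes: Iterable[str]) -> "Interactome":
        return Interactome(nx.Graph(self._g.subgraph(nodes)))

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class GeneSet:
    """Named, ordered, duplicate-free list of gene symbols."""

    name: str
    members: tuple[str, ...]
    _member_set: frozenset = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        members = tuple(self.members)
        if len(set(members)) != len(members):
            raise ValueError(f"gene set {self.name!r} contains duplicates")
        if any(not isinstance(m, str) or not m for m in members):
            raise ValueError(f"gene set {self.name!r} has invalid symbols")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "_member_set", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self._member_set


def _open(source: Source):
    """Return (stream, should_close)."""
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_edge_list(source: Source, comment_prefix: str = "#") -> Interactome:
    """Parse a two-column edge list into an :class:`Interactome`.

    Duplicate lines and reversed duplicates collapse to a single edge.
    Self-loop lines are dropped with a warning. Columns beyond the first two
    are ignored. Raises ``ValueError`` on malformed lines (naming the line
    number) or if no edge survives.
    """
    stream, close = _open(source)
    g = nx.Graph()
    dropped = 0
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"line {lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            a, b = tokens[0], tokens[1]
            if a == b:
                dropped += 1
                logger.warning("line %d: dropped self-loop on %s", lineno, a)
                continue
            g.add_edge(a, b)
    finally:
        if close:
            stream.close()
    if g.number_of_edges() == 0:
        raise ValueError("edge list contains no valid edges")
    if dropped:
        logger.info("dropped %d self-loop line(s)", dropped)
    return Interactome(g)


def write_edge_list(net: Interactome, sink: Source) -> None:
    """Write the interactome as a deterministic two-column TSV."""
    stream, close = (open(sink, "w", encoding="utf-8"), True) if isinstance(
        sink, (str, Path)
    ) else (sink, False)
    try:
        for a, b in net.edges():
            stream.write(f"{a}\t{b}\n")
    finally:
        if close:
            stream.close()


def read_gene_set(source: Source, name: str) -> GeneSet:
    """Read a one-symbol-per-line gene set; duplicates keep first occurrence."""
    stream, close = _open(source)
    seen: dict[str, None] = {}
    try:
        for raw in stream:
            symbol = raw.strip()
            if symbol:
                seen.setdefault(symbol, None)
    finally:
        if close:
            stream.close()
    if not seen:
        raise ValueError(f"gene set {name!r} is empty")
    return GeneSet(name=name, members=tuple(seen))


def write_gene_set(genes: GeneSet, sink: Source) -> None:
    stream, close = (open(sink, "w", encoding="utf-8"), True) if isinstance(
        sink, (str, Path)
    ) else (sink, False)
    try:
        for g in genes:
            stream.write(f"{g}\n")
    finally:
        if close:
            stream.close()


def largest_connected_component(net: Interactome) -> Interactome:
    """Induced subgraph on the largest component.

    Per-node average shortest path length is only well-defined when every
    other node is reachable, so the analysis runs on this subgraph by
    default. Ties in component size break toward the component containing
    the lexicographically smallest symbol.
    """
    if net.n_nodes == 0:
        raise ValueError("empty graph has no components")
    components = nx.connected_components(net.to_networkx())
    best = min(components, key=lambda c: (-len(c), min(c)))
    return net.subgraph(best)


def first_order_neighbors(
    net: Interactome, seeds: GeneSet, include_seeds: bool = False
) -> GeneSet:
    """Union of the adjacency sets of the seed genes.

    By default the seeds themselves are removed so that neighbor statistics
    are not contaminated by the seed genes. Seeds absent from the network
    are skipped with a warning; if none is present, raises ``ValueError``.
    """
    present = [g for g in seeds if g in net]
    absent = [g for g in seeds if g not in net]
    if absent:
        logger.warning(
            "%d seed gene(s) absent from network (e.g. %s)", len(absent), absent[:5]
        )
    if not present:
        raise ValueError(f"no seed gene of {seeds.name!r} is present in the network")
    union: set[str] = set()
    for g in present:
        union |= net.neighbors(g)
    if include_seeds:
        union |= set(present)
    else:
        union -= set(seeds.members)
    return GeneSet(name=f"{seeds.name}_neighbors", members=tuple(sorted(union)))


def write_metrics_table(records, sink: Source) -> None:
    """Serialize per-gene metrics as TSV (gene/degree/aspl/cc/bc).

    Floats are rendered with 6 significant digits; row order is input order.
    """
    records = list(records)
    if not records:
        raise ValueError("no metrics records to write")
    df = pd.DataFrame(
        [(r.gene, r.degree, r.aspl, r.cc, r.bc) for r in records],
        columns=list(METRICS_COLUMNS),
    )
    text = df.to_csv(sep="\t", index=False, float_format="%.6g")
    stream, close = (open(sink, "w", encoding="utf-8"), True) if isinstance(
        sink, (str, Path)
    ) else (sink, False)
    try:
        stream.write(text)
    finally:
        if close:
            stream.close()


def read_metrics_table(source: Source):
    """Read a TSV produced by :func:`write_metrics_table` back into records."""
    from .metrics import NodeMetrics

    stream, close = _open(source)
    try:
        df = pd.read_csv(stream, sep="\t")
    finally:
        if close:
            stream.close()
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    return [
        NodeMetrics(
            gene=str(row.gene),
            degree=int(row.degree),
            aspl=float(row.aspl),
            cc=float(row.cc),
            bc=float(row.bc),
        )
        for row in df.itertuples(index=False)
    ]
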