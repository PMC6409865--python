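"""Independent brute-force oracles used only by the test suite.

Each oracle computes the same quantity as the library by a different
route: dynamic programming over the full distance matrix, literal
enumeration of shortest paths, full enumeration of the rank-sum
permutation null, or hand-built average ranks. They deliberately share no
code with the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall

import netloci as nl


def random_gnp(seed: int, n_max: int = 30, p: float = 0.25) -> nl.Interactome:
    """Seeded Erdos-Renyi interactome with at least one edge."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    while True:
        edges = [
            (f"n{i:02d}", f"n{j:02d}")
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        if edges:
            return nl.Interactome.from_edges(edges)


def random_connected_gnp(seed: int, n_max: int = 30, p: float = 0.3) -> nl.Interactome:
    for attempt in range(1000):
        net = random_gnp(seed * 1000 + attempt, n_max=n_max, p=p)
        net = nl.largest_connected_component(net)
        if net.n_nodes >= 4:
            return net
    raise RuntimeError("could not build a connected test graph")


def floyd_warshall_distances(net: nl.Interactome) -> dict[str, dict[str, float]]:
    """All-pairs hop distances by dense dynamic programming."""
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    mat = np.full((len(nodes), len(nodes)), np.inf)
    np.fill_diagonal(mat, 0.0)
    for a, b in net.edges():
        mat[index[a], index[b]] = 1.0
        mat[index[b], index[a]] = 1.0
    dist = floyd_warshall(mat, directed=False)
    return {
        a: {b: dist[index[a], index[b]] for b in nodes} for a in nodes
    }


def brute_betweenness(net: nl.Interactome, normalized: bool = True) -> dict[str, float]:
    """Betweenness by literally enumerating every shortest path of every pair."""
    g = net.to_networkx()
    nodes = sorted(net.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for i, j in combinations(nodes, 2):
        if not nx.has_path(g, i, j):
            continue
        paths = list(nx.all_shortest_paths(g, i, j))
        for v in nodes:
            if v in (i, j):
                continue
            through = sum(1 for path in paths if v in path)
            if through:
                bc[v] += through / len(paths)
    if normalized:
        n = len(nodes)
        scale = (n - 1) * (n - 2) / 2
        if scale > 0:
            bc = {v: b / scale for v, b in bc.items()}
    return bc


def brute_mannwhitney_two_sided(xs, ys) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments."""
    m, n = len(xs), len(ys)
    pooled = list(xs) + list(ys)

    def u_statistic(x_idx: tuple[int, ...]) -> float:
        x_vals = [pooled[i] for i in x_idx]
        y_vals = [pooled[i] for i in range(m + n) if i not in set(x_idx)]
        u = 0.0
        for xv in x_vals:
            for yv in y_vals:
                if xv > yv:
                    u += 1.0
                elif xv == yv:
                    u += 0.5
        return u

    observed = u_statistic(tuple(range(m)))
    dist = [u_statistic(c) for c in combinations(range(m + n), m)]
    total = len(dist)
    lo = sum(1 for u in dist if u <= observed) / total
    hi = sum(1 for u in dist if u >= observed) / total
    return observed, min(1.0, 2 * min(lo, hi))


def brute_mannwhitney_tie_free(xs, ys) -> tuple[float, float]:
    """Exact two-sided p for tie-free samples by enumerating rank positions.

    With no ties, U is determined by which sorted positions the x-sample
    occupies; the full permutation null is the C(m+n, m) position choices.
    """
    m, n = len(xs), len(ys)
    pooled = sorted(xs + ys)
    assert len(set(pooled)) == m + n, "oracle requires tie-free data"
    positions = {v: i for i, v in enumerate(pooled)}
    observed = sum(positions[x] for x in xs) - m * (m - 1) // 2
    dist = [
        sum(c) - m * (m - 1) // 2 for c in combinations(range(m + n), m)
    ]
    total = len(dist)
    lo = sum(1 for u in dist if u <= observed) / total
    hi = sum(1 for u in dist if u >= observed) / total
    return float(observed), min(1.0, 2 * min(lo, hi))


def handbuilt_average_ranks(values) -> list[float]:
    """Average ranks built from sorted positions, no library calls."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # positions are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(xs, ys) -> float:
    """Textbook product-moment correlation."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


def brute_spearman(xs, ys) -> float:
    return pearson(handbuilt_average_ranks(xs), handbuilt_average_ranks(ys))
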