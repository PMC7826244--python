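"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: betweenness by
exhaustive geodesic enumeration, components by union-find, distances by
Floyd-Warshall on a dense matrix.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def union_find_components(nodes, edges):
    """Connected components via a plain disjoint-set union."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return list(groups.values())


def floyd_warshall_distances(nodes, edges):
    """All-pairs unweighted distances; math.inf for unreachable pairs."""
    order = sorted(nodes)
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in edges:
        d[idx[a], idx[b]] = 1.0
        d[idx[b], idx[a]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return {
        (u, v): (d[idx[u], idx[v]] if np.isfinite(d[idx[u], idx[v]]) else math.inf)
        for u in order
        for v in order
    }


def enumerate_geodesics(g: nx.Graph, s, t):
    """All shortest s-t paths by exhaustive simple-path enumeration."""
    try:
        target = nx.shortest_path_length(g, s, t)
    except nx.NetworkXNoPath:
        return set()
    return {
        tuple(p)
        for p in nx.all_simple_paths(g, s, t, cutoff=target)
        if len(p) - 1 == target
    }


def exhaustive_betweenness(g: nx.Graph, normalized: bool = True):
    """Betweenness by enumerating every geodesic of every unordered pair."""
    nodes = sorted(g.nodes)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_geodesics(g, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for p in paths:
            for v in p[1:-1]:
                raw[v] += 1.0 / sigma
    n = len(nodes)
    if normalized:
        denom = (n - 1) * (n - 2) / 2
        if denom <= 0:
            return dict.fromkeys(nodes, 0.0)
        return {v: raw[v] / denom for v in nodes}
    return raw


def random_simple_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Seeded Erdos-Renyi graph with every node present."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
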