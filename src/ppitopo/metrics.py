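"""Node centralities and whole-network statistics.

Three per-node quantities drive the analysis: degree (number of interaction
partners), betweenness centrality (fraction of all-pairs geodesics passing
through the node, endpoints excluded — the "bottleneck" score) and closeness
centrality (reciprocal of the node's mean geodesic distance within its
component — the "topological centre" score). Network-level summaries are the
average degree, the mean shortest path length over connected pairs, and the
diameter.

Betweenness is computed with Brandes' dependency-accumulation algorithm and
normalized by (n-1)(n-2)/2, the undirected-graph pair count; closeness is
computed within each node's component. Both conventions match what the
common interactive network-analysis tools report for disease PPI networks,
so values are comparable with published centrality tables.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx

from .graph_core import Network

logger = logging.getLogger(__name__)

__all__ = [
    "NodeMetrics",
    "NetworkSummary",
    "degree_map",
    "betweenness_centrality",
    "closeness_centrality",
    "network_summary",
    "compute_node_metrics",
    "write_node_metrics",
]


@dataclass(frozen=True)
class NodeMetrics:
    """Centrality record for one node: degree, normalized betweenness, closeness."""

    symbol: str
    degree: int
    betweenness: float
    closeness: float


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network statistics.

    ``avg_degree`` is 2E/N over all nodes; ``mspl`` and ``diameter`` are the
    mean and maximum geodesic length over *connected* unordered node pairs
    (extended PPI networks are typically disconnected, so unreachable pairs
    are excluded rather than treated as infinite).
    """

    n_nodes: int
    n_edges: int
    avg_degree: float
    mspl: float
    diameter: int


def degree_map(net: Network) -> dict[str, int]:
    """Degree of every node; isolated nodes map to 0."""
    return {v: int(net.graph.degree[v]) for v in net.nodes}


def betweenness_centrality(net: Network, normalized: bool = True) -> dict[str, float]:
    """Betweenness centrality of every node (Brandes' algorithm).

    For each node v, the raw score is the sum over unordered pairs
    (s, t), s != v != t, of sigma_st(v) / sigma_st — the fraction of
    geodesics between s and t that pass through v. Disconnected pairs
    contribute nothing. With ``normalized`` the raw score is divided by
    (n-1)(n-2)/2, bounding it to [0, 1]; a score of 1 means every
    geodesic between every other pair runs through the node.
    """
    g = net.graph
    nodes = net.nodes
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest paths: BFS with path counting
        sigma = dict.fromkeys(nodes, 0)
        sigma[s] = 1
        dist = {s: 0}
        preds: dict[str, list[str]] = {v: [] for v in nodes}
        order: list[str] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation, farthest-first
        delta = dict.fromkeys(nodes, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    n = len(nodes)
    # each unordered pair was accumulated from both endpoints
    scale = (n - 1) * (n - 2) if normalized else 2.0
    if scale <= 0:
        return dict.fromkeys(nodes, 0.0)
    return {v: bc[v] / scale for v in nodes}


def closeness_centrality(net: Network) -> dict[str, float]:
    """Closeness centrality within each node's component.

    CC(v) = (r - 1) / sum of geodesic distances from v to the other r - 1
    nodes of its component, i.e. the reciprocal of v's mean geodesic
    length; isolated nodes get 0. No cross-component penalty is applied.
    """
    return {
        v: float(c)
        for v, c in nx.closeness_centrality(net.graph, wf_improved=False).items()
    }


def network_summary(net: Network) -> NetworkSummary:
    """Average degree, mean shortest path length and diameter.

    mspl and diameter are taken over connected unordered pairs only. An
    edgeless network has no such pairs; both are reported as 0 with a
    warning.

    Raises
    ------
    ValueError
        If the network is empty.
    """
    n, e = net.n_nodes, net.n_edges
    if n == 0:
        raise ValueError("network_summary requires a network with at least one node")
    total = 0
    pairs = 0
    diam = 0
    for _, dists in nx.all_pairs_shortest_path_length(net.graph):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
                if d > diam:
                    diam = d
    pairs //= 2  # each unordered pair seen from both ends
    total //= 2
    if pairs == 0:
        logger.warning("network has no connected pairs; mspl and diameter set to 0")
        mspl = 0.0
    else:
        mspl = total / pairs
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        avg_degree=2.0 * e / n,
        mspl=mspl,
        diameter=diam,
    )


def compute_node_metrics(net: Network) -> list[NodeMetrics]:
    """One record per node combining degree, normalized betweenness, closeness.

    Ordered by descending degree, ties broken lexicographically by symbol.
    """
    deg = degree_map(net)
    bc = betweenness_centrality(net, normalized=True)
    cc = closeness_centrality(net)
    records = [
        NodeMetrics(symbol=v, degree=deg[v], betweenness=bc[v], closeness=cc[v])
        for v in net.nodes
    ]
    records.sort(key=lambda r: (-r.degree, r.symbol))
    return records


def write_node_metrics(metrics: list[NodeMetrics], path) -> None:
    """Write a node-metric table as TSV with 8-decimal fixed-format reals."""
    with open(path, "w") as fh:
        fh.write("symbol\tdegree\tbetweenness\tcloseness\n")
        for m in metrics:
            fh.write(f"{m.symbol}\t{m.degree}\t{m.betweenness:.8f}\t{m.closeness:.8f}\n")
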