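"""Undirected simple-graph model and path primitives.

Every downstream stage (centralities, backbone extraction, shortest-path
subnetworks, resampling validation) operates on the :class:`Network` defined
here: an undirected, unweighted, simple graph whose nodes are gene symbols.
Interaction confidence scores are consumed only at ingestion time as a
filter; once a network is built, all quantities are plain-graph quantities.

The class wraps a :class:`networkx.Graph` and enforces the invariants the
analysis relies on: canonical uppercase symbols, no self-loops, no parallel
edges, deterministic (lexicographic) iteration order so that every derived
artifact is byte-stable.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidSymbolError",
    "Network",
    "canonical_symbol",
    "build_network",
    "connected_components",
    "giant_component",
    "shortest_path_lengths",
    "all_shortest_paths",
]


class InvalidSymbolError(ValueError):
    """Raised for gene symbols that are empty or contain whitespace."""


def canonical_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol to its uppercase HGNC-style form.

    Comparison throughout the package is case-insensitive; the canonical
    form stored on networks is uppercase with surrounding whitespace
    stripped.

    Raises
    ------
    InvalidSymbolError
        If the symbol is empty after stripping or contains internal
        whitespace.
    """
    if not isinstance(symbol, str):
        raise InvalidSymbolError(f"gene symbol must be a string, got {symbol!r}")
    s = symbol.strip()
    if not s:
        raise InvalidSymbolError(f"empty gene symbol: {symbol!r}")
    if any(c.isspace() for c in s):
        raise InvalidSymbolError(f"gene symbol contains whitespace: {symbol!r}")
    return s.upper()


class Network:
    """Undirected simple graph over canonical gene symbols.

    Thin immutable-by-convention wrapper around :class:`networkx.Graph`.
    Construction goes through :func:`build_network` (or the module's other
    factories), which canonicalizes symbols, drops self-loops and collapses
    duplicate edges. Node and edge accessors return sorted tuples so that
    iteration order — and hence every file written from a network — is
    deterministic.
    """

    __slots__ = ("_g",)

    def __init__(self, graph: nx.Graph):
        self._g = graph

    # -- accessors -----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (do not mutate)."""
        return self._g

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._g.nodes))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(tuple(sorted(e)) for e in self._g.edges))

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, symbol: str) -> bool:
        return self._g.has_node(symbol)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def degree(self, symbol: str) -> int:
        return int(self._g.degree[symbol])

    def neighbors(self, symbol: str) -> tuple[str, ...]:
        return tuple(sorted(self._g.neighbors(symbol)))

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        """Induced subgraph on ``nodes`` (all must be present)."""
        return Network(nx.Graph(self._g.subgraph(nodes)))

    def __contains__(self, symbol: str) -> bool:
        return self._g.has_node(symbol)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def build_network(
    edges: Iterable[tuple[str, str]],
    extra_nodes: Iterable[str] = (),
) -> Network:
    """Build a simple undirected network from edge pairs.

    Self-loops are dropped and duplicate pairs (in either orientation)
    collapsed, with a logged count of each; symbols are canonicalized.
    ``extra_nodes`` are added as isolated nodes when not already present.

    Raises
    ------
    InvalidSymbolError
        If any endpoint or extra node is a malformed symbol.
    """
    g = nx.Graph()
    n_loops = 0
    n_dups = 0
    for a, b in edges:
        ca, cb = canonical_symbol(a), canonical_symbol(b)
        if ca == cb:
            n_loops += 1
            continue
        if g.has_edge(ca, cb):
            n_dups += 1
            continue
        g.add_edge(ca, cb)
    for sym in extra_nodes:
        g.add_node(canonical_symbol(sym))
    if n_loops:
        logger.info("dropped %d self-loop(s)", n_loops)
    if n_dups:
        logger.info("collapsed %d duplicate edge(s)", n_dups)
    return Network(g)


def connected_components(net: Network) -> list[frozenset[str]]:
    """Partition the node set into maximal connected sets.

    Ordered by decreasing size; ties broken by the lexicographically
    smallest member. The empty network yields an empty list.
    """
    comps = [frozenset(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def giant_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    The giant component is the object of all downstream topology analysis;
    smaller detached components are discarded at this step.

    Raises
    ------
    ValueError
        If the network has no nodes.
    """
    if net.n_nodes == 0:
        raise ValueError("giant_component requires a network with at least one node")
    return net.subgraph(connected_components(net)[0])


def shortest_path_lengths(net: Network, source: str) -> Mapping[str, int]:
    """Unweighted geodesic distances from ``source`` to every reachable node.

    Unreachable nodes are absent from the returned map; the distance to the
    source itself is 0.
    """
    source = canonical_symbol(source)
    if source not in net:
        raise ValueError(f"source node {source!r} not in network")
    return dict(nx.single_source_shortest_path_length(net.graph, source))


def all_shortest_paths(net: Network, s: str, t: str) -> set[tuple[str, ...]]:
    """Every geodesic between ``s`` and ``t``, as node tuples.

    Returns the complete set of shortest paths, not one representative —
    the shortest-path subnetwork stage depends on getting all of them.
    Returns the empty set when ``t`` is unreachable from ``s``.

    Raises
    ------
    ValueError
        If ``s`` equals ``t`` or either node is absent.
    """
    s, t = canonical_symbol(s), canonical_symbol(t)
    if s == t:
        raise ValueError("source and target must differ")
    for node in (s, t):
        if node not in net:
            raise ValueError(f"node {node!r} not in network")
    try:
        return {tuple(p) for p in nx.all_shortest_paths(net.graph, s, t)}
    except nx.NetworkXNoPath:
        return set()
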