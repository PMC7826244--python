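"""The seven-step topology-analysis procedure for disease gene networks.

Starting from a curated candidate-gene ("seed") list and a scored
interaction table, the pipeline

1. grows the *extended network*: seeds plus their direct interaction
   partners, with every qualifying edge among the included nodes;
2. extracts the *giant component*, the object of all further analysis;
3. computes per-node centralities and selects *key nodes* — the top
   fraction by degree and by betweenness, and their intersection (nodes
   that are both hubs and bottlenecks);
4. builds the *backbone*: the induced subgraph on the top-k
   betweenness nodes, the heavily used crossing points of the network;
5. builds the *shortest-path subnetwork*: the induced subgraph on the
   union of all geodesics between every pair of candidate genes;
6. *validates* the backbone by resampling seed subsets, rebuilding the
   network, and measuring how often each backbone node reappears among
   the top-k betweenness nodes of the replicate.

Cutoff ties are always included in full (with the effective k recorded)
rather than broken arbitrarily, so every ranking artifact is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Iterable, Sequence
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np

from .graph_core import Network, build_network, canonical_symbol, giant_component
from .metrics import NodeMetrics, betweenness_centrality

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import InteractionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SeedList",
    "BackboneResult",
    "PathSubnetwork",
    "ValidationReport",
    "build_extended_network",
    "select_key_nodes",
    "key_node_intersection",
    "build_backbone",
    "shortest_path_subnetwork",
    "validate_backbone",
]


@dataclass(frozen=True)
class SeedList:
    """Ordered list of unique candidate gene symbols."""

    genes: tuple[str, ...]

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "SeedList":
        """Canonicalize and deduplicate, preserving first-seen order."""
        seen: dict[str, None] = {}
        n_dups = 0
        for s in symbols:
            c = canonical_symbol(s)
            if c in seen:
                n_dups += 1
            else:
                seen[c] = None
        if not seen:
            raise ValueError("seed list is empty")
        if n_dups:
            logger.warning("collapsed %d duplicate seed symbol(s)", n_dups)
        return cls(genes=tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes


@dataclass(frozen=True)
class BackboneResult:
    """Top-k-betweenness backbone: the selected ranking and its induced subgraph."""

    backbone: Network
    selected: tuple[tuple[str, float], ...]
    k_requested: int
    k_effective: int


@dataclass(frozen=True)
class PathSubnetwork:
    """Induced subgraph on the union of all geodesics between candidate genes."""

    subnet: Network
    candidate_pairs_connected: int
    candidate_pairs_total: int


@dataclass(frozen=True)
class ValidationReport:
    """Per-backbone-node frequency of reappearing in resampled top-k rankings."""

    frequencies: dict[str, float]
    n_replicates: int
    seed_fraction: float
    rng_seed: int


def build_extended_network(
    seeds: SeedList,
    interactions: Sequence["InteractionRecord"],
    min_score: float = 0.0,
) -> Network:
    """Seeds plus first neighbors, with all qualifying edges among them.

    Edges with score below ``min_score`` (0-1000 combined-score scale) are
    discarded first. The node set is the seeds together with every direct
    neighbor of a seed; the edge set is every retained edge whose *both*
    endpoints fall in that node set, i.e. the full induced subgraph —
    seed-seed, seed-neighbor and neighbor-neighbor links alike. Seeds with
    no qualifying interaction remain as isolated nodes (warned about), so
    no candidate silently disappears.
    """
    if not interactions:
        raise ValueError("interaction table is empty")
    seed_set = set(seeds.genes)
    kept: list[tuple[str, str]] = []
    for rec in interactions:
        if rec.score < min_score:
            continue
        a, b = canonical_symbol(rec.protein_a), canonical_symbol(rec.protein_b)
        if a != b:
            kept.append((a, b))
    adjacency: dict[str, set[str]] = {}
    for a, b in kept:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    included = set(seed_set)
    for s in seed_set:
        included |= adjacency.get(s, set())
    missing = sorted(s for s in seed_set if s not in adjacency)
    if missing:
        logger.warning(
            "%d seed(s) have no qualifying interaction and stay isolated: %s",
            len(missing), ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
    edges = [(a, b) for a, b in kept if a in included and b in included]
    return build_network(edges, extra_nodes=included)


def select_key_nodes(
    metrics: Sequence[NodeMetrics],
    criterion: str,
    fraction: float = 0.10,
) -> list[str]:
    """Top fraction of nodes by degree or betweenness, ties at the cutoff included.

    ``criterion`` is ``"degree"`` or ``"betweenness"`` (``"bc"`` accepted).
    Takes the top ``ceil(fraction * n)`` nodes in descending order of the
    criterion; every node tied with the value at the cutoff is also
    included. Secondary order is lexicographic by symbol.
    """
    if not metrics:
        raise ValueError("metrics list is empty")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    crit = criterion.lower()
    if crit in ("degree", "k"):
        value = lambda m: m.degree
    elif crit in ("betweenness", "bc"):
        value = lambda m: m.betweenness
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    ranked = sorted(metrics, key=lambda m: (-value(m), m.symbol))
    k = math.ceil(fraction * len(ranked))
    cutoff = value(ranked[k - 1])
    return [m.symbol for m in ranked if value(m) > cutoff] + [
        m.symbol for m in ranked if value(m) == cutoff
    ]


def key_node_intersection(
    by_degree: Iterable[str], by_betweenness: Iterable[str]
) -> set[str]:
    """Nodes that are simultaneously hubs (high degree) and bottlenecks (high BC)."""
    return set(by_degree) & set(by_betweenness)


def build_backbone(net: Network, k: int = 15) -> BackboneResult:
    """Induced subgraph on the top-k nodes by normalized betweenness.

    Nodes tied with the k-th betweenness value are all included and the
    effective k recorded. ``k`` larger than the node count is clamped with
    a warning, returning the whole network.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = net.n_nodes
    if k > n:
        logger.warning("backbone k=%d exceeds node count %d; clamping", k, n)
        k = n
    bc = betweenness_centrality(net, normalized=True)
    ranked = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ranked[k - 1][1]
    selected = tuple((v, c) for v, c in ranked if c >= cutoff)
    nodes = [v for v, _ in selected]
    return BackboneResult(
        backbone=net.subgraph(nodes),
        selected=selected,
        k_requested=k,
        k_effective=len(selected),
    )


def shortest_path_subnetwork(net: Network, candidates: SeedList) -> PathSubnetwork:
    """Induced subgraph on all geodesics between pairs of candidate genes.

    For every unordered pair of candidates that are both present in the
    network and mutually reachable, *all* shortest paths are collected;
    the subnetwork is the induced subgraph on the union of their nodes.
    Candidates in the network always appear in the subnetwork, isolated if
    unreachable from every other candidate. Pairs split across components
    count toward ``candidate_pairs_total`` but not
    ``candidate_pairs_connected``.
    """
    present = [c for c in candidates if c in net]
    keep: set[str] = set(present)
    connected = 0
    total = 0
    g = net.graph
    for i, s in enumerate(present):
        # one BFS-predecessor pass per source covers all targets after it
        preds, _ = nx.predecessor(g, s, return_seen=True)
        for t in present[i + 1 :]:
            total += 1
            if t not in preds and t != s:
                continue
            connected += 1
            # walk predecessor DAG from t back to s, collecting all nodes
            stack = [t]
            seen_back = {t}
            while stack:
                v = stack.pop()
                keep.add(v)
                for p in preds.get(v, ()):
                    if p not in seen_back:
                        seen_back.add(p)
                        stack.append(p)
    return PathSubnetwork(
        subnet=net.subgraph(keep),
        candidate_pairs_connected=connected,
        candidate_pairs_total=total,
    )


def validate_backbone(
    interactions: Sequence["InteractionRecord"],
    seeds: SeedList,
    backbone_nodes: Iterable[str],
    seed_fraction: float = 0.8,
    n_replicates: int = 100,
    k: int = 15,
    rng_seed: int = 0,
    min_score: float = 0.0,
) -> ValidationReport:
    """Resampling robustness check of the backbone.

    Each replicate draws ``ceil(seed_fraction * n_seeds)`` seeds without
    replacement, rebuilds the extended network, takes its giant component,
    and records the top-k betweenness node set (ties included). The
    frequency of a backbone node is the fraction of replicates in which it
    reappears in that set — nodes whose bottleneck status survives seed
    perturbation score near 1. Fully reproducible given ``rng_seed``.
    """
    if not 0 < seed_fraction <= 1:
        raise ValueError(f"seed_fraction must be in (0, 1], got {seed_fraction}")
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    backbone_nodes = sorted(canonical_symbol(v) for v in backbone_nodes)
    rng = np.random.default_rng(rng_seed)
    genes = seeds.genes
    n_draw = math.ceil(seed_fraction * len(genes))
    hits = dict.fromkeys(backbone_nodes, 0)
    for _ in range(n_replicates):
        idx = rng.choice(len(genes), size=n_draw, replace=False)
        subset = SeedList.from_symbols(genes[i] for i in sorted(idx))
        extended = build_extended_network(subset, interactions, min_score=min_score)
        replicate_giant = giant_component(extended)
        top = build_backbone(replicate_giant, k=min(k, replicate_giant.n_nodes))
        top_set = {v for v, _ in top.selected}
        for v in backbone_nodes:
            if v in top_set:
                hits[v] += 1
    return ValidationReport(
        frequencies={v: hits[v] / n_replicates for v in backbone_nodes},
        n_replicates=n_replicates,
        seed_fraction=seed_fraction,
        rng_seed=rng_seed,
    )
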