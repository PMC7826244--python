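"""Generators for networks and interaction tables with known structure.

Real disease PPI edge lists come from interaction databases whose snapshots
are rarely archived alongside a study, so the pipeline is exercised against
synthetic inputs with the statistical features the analysis assumes:

* a heavy-tailed, hub-dominated degree distribution (preferential
  attachment), since PPI networks carry a few very highly connected
  proteins among many sparsely connected ones;
* confidence-scored edge tables in the 0-1000 combined-score convention,
  so the ingestion filter is exercised;
* a designated seed subset standing in for a curated candidate-gene list;
* planted bottleneck nodes — bridge nodes between two dense cliques —
  whose betweenness is maximal by construction, giving the backbone and
  validation stages a known ground truth to recover.

All generators are pure functions of their parameters plus an RNG seed:
identical calls produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import Network, build_network
from .pipeline import SeedList

__all__ = [
    "InteractionRecord",
    "SyntheticSpec",
    "generate_scale_free",
    "generate_planted_bottleneck",
    "emit_interaction_table",
    "sample_seed_list",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One scored candidate interaction (combined score on the 0-1000 scale)."""

    protein_a: str
    protein_b: str
    score: int

    def __post_init__(self):
        if not 0 <= self.score <= 1000:
            raise ValueError(f"score must be in 0..1000, got {self.score}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic PPI benchmark.

    Defaults mirror a curated-disease-network setting: 208 nodes (the size
    of a literature-curated oral-cancer candidate list and of its giant
    interaction component) with attachment 8, which yields ~1630 edges and
    an average degree near 15 — the density regime of such networks. Scores
    span 400-999, i.e. medium-to-high confidence.
    """

    n_nodes: int = 208
    attachment: int = 8
    n_seeds: int = 208
    planted_bottlenecks: int = 0
    score_low: int = 400
    score_high: int = 999
    rng_seed: int = 0

    def __post_init__(self):
        if self.attachment < 1:
            raise ValueError("attachment must be >= 1")
        if self.n_nodes <= self.attachment:
            raise ValueError("n_nodes must exceed attachment")
        if not 0 < self.n_seeds <= self.n_nodes:
            raise ValueError("n_seeds must be in 1..n_nodes")


def _symbol(i: int, prefix: str = "G") -> str:
    return f"{prefix}{i:04d}"


def generate_scale_free(spec: SyntheticSpec) -> Network:
    """Preferential-attachment (Barabási–Albert-style) network.

    Starts from a clique of ``attachment + 1`` nodes; each subsequent node
    attaches to ``attachment`` distinct existing nodes with probability
    proportional to their current degree. The result is connected with
    exactly C(m+1, 2) + m * (n - m - 1) edges for m = attachment, and a
    heavy-tailed degree distribution dominated by the early hubs.
    """
    rng = np.random.default_rng(spec.rng_seed)
    m = spec.attachment
    symbols = [_symbol(i + 1) for i in range(spec.n_nodes)]
    edges: list[tuple[str, str]] = []
    # degree-weighted sampling via the repeated-endpoints trick
    repeated: list[str] = []
    core = symbols[: m + 1]
    for i, a in enumerate(core):
        for b in core[i + 1 :]:
            edges.append((a, b))
            repeated.extend((a, b))
    for new in symbols[m + 1 :]:
        targets: set[str] = set()
        while len(targets) < m:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        for t in sorted(targets):
            edges.append((new, t))
            repeated.extend((new, t))
    return build_network(edges)


def generate_planted_bottleneck(
    clique_size: int, n_bridges: int, rng_seed: int = 0
) -> tuple[Network, frozenset[str]]:
    """Two cliques joined through a chain of bridge nodes.

    Every geodesic between the cliques must traverse the whole bridge
    chain, so each bridge node has strictly higher raw betweenness than any
    clique node — a planted bottleneck with known ground truth. The RNG
    seed picks which clique member anchors each end of the chain (the
    structure is anchor-invariant; the seed only varies the labelling).

    Returns the network and the set of planted bridge symbols, which are
    exactly the degree-2 nodes connecting the cliques.
    """
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    if n_bridges < 1:
        raise ValueError("n_bridges must be >= 1")
    rng = np.random.default_rng(rng_seed)
    left = [_symbol(i + 1, "L") for i in range(clique_size)]
    right = [_symbol(i + 1, "R") for i in range(clique_size)]
    bridges = [_symbol(i + 1, "B") for i in range(n_bridges)]
    edges: list[tuple[str, str]] = []
    for clique in (left, right):
        for i, a in enumerate(clique):
            for b in clique[i + 1 :]:
                edges.append((a, b))
    chain = [left[int(rng.integers(clique_size))], *bridges,
             right[int(rng.integers(clique_size))]]
    edges.extend(zip(chain, chain[1:]))
    return build_network(edges), frozenset(bridges)


def emit_interaction_table(
    net: Network,
    score_low: int = 400,
    score_high: int = 999,
    rng_seed: int = 0,
    reversed_fraction: float = 0.0,
) -> list[InteractionRecord]:
    """Emit one scored record per edge, database-export style.

    Scores are uniform random integers in [score_low, score_high]. With
    ``reversed_fraction`` > 0 that fraction of records is additionally
    duplicated in reversed orientation (as real exports often list both
    directions), exercising loader deduplication.
    """
    if not 0 <= score_low <= score_high <= 1000:
        raise ValueError("need 0 <= score_low <= score_high <= 1000")
    rng = np.random.default_rng(rng_seed)
    records = [
        InteractionRecord(a, b, int(rng.integers(score_low, score_high + 1)))
        for a, b in net.edges
    ]
    if reversed_fraction > 0:
        flip = rng.random(len(records)) < reversed_fraction
        records.extend(
            InteractionRecord(r.protein_b, r.protein_a, r.score)
            for r, f in zip(list(records), flip)
            if f
        )
    return records


def sample_seed_list(net: Network, n_seeds: int, rng_seed: int = 0) -> SeedList:
    """Uniform sample of ``n_seeds`` nodes without replacement, reproducible."""
    nodes = net.nodes
    if n_seeds > len(nodes):
        raise ValueError(f"n_seeds={n_seeds} exceeds node count {len(nodes)}")
    rng = np.random.default_rng(rng_seed)
    picked = rng.choice(len(nodes), size=n_seeds, replace=False)
    return SeedList.from_symbols(nodes[i] for i in sorted(picked))
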