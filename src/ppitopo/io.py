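"""Readers, writers, packaged reference tables, and the end-to-end runner.

Supported on-disk formats are deliberately plain text:

* seed gene lists — one symbol per line, or the first column of a TSV;
* interaction tables — SIF (``A<TAB>rel<TAB>B``, implying full confidence)
  or STRING-style TSV (``protein1  protein2  combined_score`` with the
  score on the 0-1000 scale);
* networks — SIF out/in (sorted, byte-stable) and GraphML (export only);
* metric and validation tables — TSV; run summaries — JSON.

The package ships three small reference tables from a published
oral-cancer PPI study: the 208-gene candidate list, the ten nodes reported
as both hubs and bottlenecks, and the reported top-15 rankings by degree,
closeness and betweenness. They serve as worked examples and ranking
fixtures; reproducing the underlying interaction snapshot is not possible
(it was never deposited), so they are inputs, not regression baselines.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .graph_core import (
    Network,
    build_network,
    canonical_symbol,
    giant_component,
)
from .metrics import (
    NodeMetrics,
    compute_node_metrics,
    network_summary,
    write_node_metrics,
)
from .pipeline import (
    SeedList,
    build_backbone,
    build_extended_network,
    key_node_intersection,
    select_key_nodes,
    shortest_path_subnetwork,
    validate_backbone,
)
from .synthetic_data import InteractionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_seed_genes",
    "load_interactions",
    "read_network",
    "write_network",
    "oral_cancer_candidate_genes",
    "reported_key_nodes",
    "reported_rankings",
    "run_pipeline",
]

_DIALECTS = ("sif", "string_tsv")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full pipeline run.

    ``min_score`` follows the common medium-confidence convention (400 on
    the 0-1000 combined-score scale); ``backbone_k`` and ``key_fraction``
    are the customary top-15 / top-10% cutoffs for backbone extraction and
    key-node selection; validation defaults to 100 replicates at 80% seed
    retention.
    """

    min_score: float = 400.0
    backbone_k: int = 15
    key_fraction: float = 0.10
    seed_fraction: float = 0.8
    n_replicates: int = 100
    rng_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML or JSON mapping; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# loaders


def load_seed_genes(path: str | Path) -> SeedList:
    """Load a candidate-gene list: one symbol per line or first TSV column.

    Symbols are canonicalized to uppercase; duplicates are collapsed with a
    warning. An empty file is an error.
    """
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            symbols.append(line.split("\t")[0])
    if not symbols:
        raise ValueError(f"seed gene file {path} is empty")
    return SeedList.from_symbols(symbols)


def load_interactions(path: str | Path, dialect: str = "string_tsv") -> list[InteractionRecord]:
    """Load a scored interaction table.

    ``sif`` rows (``A<TAB>relation<TAB>B``) get score 1000; ``string_tsv``
    rows (``protein1<TAB>protein2<TAB>combined_score``) keep their integer
    score, with a header line auto-skipped. Malformed rows abort the load
    with their line numbers.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    records: list[InteractionRecord] = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                bad.append(lineno)
                continue
            a, rel_or_b, b_or_score = (p.strip() for p in parts)
            try:
                if dialect == "sif":
                    rec = InteractionRecord(
                        canonical_symbol(a), canonical_symbol(b_or_score), 1000
                    )
                else:
                    if lineno == 1 and not _is_int(b_or_score):
                        continue  # header
                    rec = InteractionRecord(
                        canonical_symbol(a), canonical_symbol(rel_or_b),
                        int(b_or_score),
                    )
            except ValueError:
                bad.append(lineno)
                continue
            records.append(rec)
    if bad:
        raise ValueError(f"malformed row(s) in {path} at line(s): {bad}")
    return records


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_network(path: str | Path) -> Network:
    """Read a network from SIF; single-token lines are isolated nodes."""
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = [p for p in line.rstrip("\n").split("\t") if p.strip()]
            if not parts:
                continue
            if len(parts) == 1:
                isolated.append(parts[0])
            elif len(parts) == 3:
                edges.append((parts[0], parts[2]))
            else:
                raise ValueError(f"malformed SIF line in {path}: {line!r}")
    return build_network(edges, extra_nodes=isolated)


def write_network(net: Network, path: str | Path, fmt: str = "sif") -> None:
    """Write a network as SIF (byte-stable) or GraphML.

    SIF edges are written as ``A<TAB>pp<TAB>B`` with A < B, sorted;
    isolated nodes follow as single-token lines, sorted.
    """
    if fmt == "sif":
        connected = {v for e in net.edges for v in e}
        with open(path, "w") as fh:
            for a, b in net.edges:
                fh.write(f"{a}\tpp\t{b}\n")
            for v in net.nodes:
                if v not in connected:
                    fh.write(f"{v}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from(net.edges)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


# ---------------------------------------------------------------------------
# packaged reference tables


def _data_path(name: str):
    return resources.files("ppitopo.data").joinpath(name)


def oral_cancer_candidate_genes() -> SeedList:
    """The packaged 208-symbol oral-cancer candidate gene list."""
    with resources.as_file(_data_path("oral_cancer_genes.txt")) as p:
        return load_seed_genes(p)


def reported_key_nodes() -> list[NodeMetrics]:
    """The ten reported hub-and-bottleneck nodes, as metric records.

    Closeness was not reported alongside this table and is set to 0; use
    :func:`reported_rankings` for the closeness ranking.
    """
    with resources.as_file(_data_path("reported_key_nodes.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        NodeMetrics(symbol=r.gene, degree=int(r.degree),
                    betweenness=float(r.betweenness), closeness=0.0)
        for r in df.itertuples()
    ]


def reported_rankings() -> pd.DataFrame:
    """Reported top-15 rankings by degree, closeness and betweenness."""
    with resources.as_file(_data_path("reported_rankings.tsv")) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# end-to-end runner


def run_pipeline(
    config: PipelineConfig,
    seed_path: str | Path,
    interaction_path: str | Path,
    out_dir: str | Path,
    dialect: str = "string_tsv",
) -> dict:
    """Run the full analysis and write every intermediate artifact.

    Stages: extended network → giant component → node metrics → key-node
    selection (degree and betweenness) and intersection → backbone →
    candidate shortest-path subnetwork → resampling validation. Outputs
    are a pure function of (config, input files): rerunning with identical
    inputs reproduces the output directory byte for byte.

    Returns the summary dict that is also written to ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    def stage(name):
        logger.info("[%7.2fs] stage: %s", time.monotonic() - t0, name)

    stage("load inputs")
    seeds = load_seed_genes(seed_path)
    interactions = load_interactions(interaction_path, dialect=dialect)

    stage("extended network")
    extended = build_extended_network(seeds, interactions, min_score=config.min_score)
    write_network(extended, out / "extended_network.sif")

    stage("giant component")
    giant = giant_component(extended)
    write_network(giant, out / "giant_component.sif")
    summary_stats = network_summary(giant)

    stage("node metrics")
    metrics = compute_node_metrics(giant)
    write_node_metrics(metrics, out / "node_metrics.tsv")

    stage("key nodes")
    by_degree = select_key_nodes(metrics, "degree", config.key_fraction)
    by_bc = select_key_nodes(metrics, "betweenness", config.key_fraction)
    both = sorted(key_node_intersection(by_degree, by_bc))
    _write_lines(out / "key_nodes_degree.txt", by_degree)
    _write_lines(out / "key_nodes_betweenness.txt", by_bc)
    _write_lines(out / "key_nodes_intersection.txt", both)

    stage("backbone")
    backbone = build_backbone(giant, k=config.backbone_k)
    write_network(backbone.backbone, out / "backbone.sif")
    with open(out / "backbone_nodes.tsv", "w") as fh:
        fh.write("symbol\tbetweenness\n")
        for v, c in backbone.selected:
            fh.write(f"{v}\t{c:.8f}\n")

    stage("shortest-path subnetwork")
    subnet = shortest_path_subnetwork(giant, seeds)
    write_network(subnet.subnet, out / "path_subnetwork.sif")

    stage("validation")
    report = validate_backbone(
        interactions,
        seeds,
        backbone_nodes=[v for v, _ in backbone.selected],
        seed_fraction=config.seed_fraction,
        n_replicates=config.n_replicates,
        k=config.backbone_k,
        rng_seed=config.rng_seed,
        min_score=config.min_score,
    )
    with open(out / "validation.tsv", "w") as fh:
        fh.write("symbol\tfrequency\n")
        for v in sorted(report.frequencies):
            fh.write(f"{v}\t{report.frequencies[v]:.4f}\n")
    with open(out / "validation.json", "w") as fh:
        json.dump(
            {
                "seed_fraction": report.seed_fraction,
                "n_replicates": report.n_replicates,
                "k": config.backbone_k,
                "rng_seed": report.rng_seed,
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    summary = {
        "config": asdict(config),
        "n_seeds": len(seeds),
        "n_interactions": len(interactions),
        "extended_network": {"nodes": extended.n_nodes, "edges": extended.n_edges},
        "giant_component": {
            "nodes": giant.n_nodes,
            "edges": giant.n_edges,
            "avg_degree": summary_stats.avg_degree,
            "mspl": summary_stats.mspl,
            "diameter": summary_stats.diameter,
        },
        "key_nodes": {
            "by_degree": by_degree,
            "by_betweenness": by_bc,
            "intersection": both,
        },
        "backbone": {
            "k_requested": backbone.k_requested,
            "k_effective": backbone.k_effective,
            "nodes": backbone.backbone.n_nodes,
            "edges": backbone.backbone.n_edges,
            "top_betweenness_node": backbone.selected[0][0],
        },
        "path_subnetwork": {
            "nodes": subnet.subnet.n_nodes,
            "edges": subnet.subnet.n_edges,
            "candidate_pairs_connected": subnet.candidate_pairs_connected,
            "candidate_pairs_total": subnet.candidate_pairs_total,
        },
        "validation": {
            "min_frequency": min(report.frequencies.values()),
            "mean_frequency": sum(report.frequencies.values()) / len(report.frequencies),
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stage("done")
    return summary


def _write_lines(path: Path, lines) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"{line}\n")
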