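# ppitopo

Topology analysis of disease protein–protein interaction (PPI) networks:
from a curated candidate-gene list and a scored interaction table to the
giant component, node centralities, the high-betweenness backbone, the
candidate shortest-path subnetwork, and a resampling-based robustness
report for the backbone.

## The problem

Disease gene lists assembled from the literature (here the shipped example
is a 208-gene oral-cancer candidate list) say little on their own about
which genes organise the disease process. Embedding the candidates in the
interactome and analysing the topology of the resulting network does:
*hubs* (high-degree nodes) interact with many partners, and *bottlenecks*
(high-betweenness nodes) sit on a large share of the network's shortest
paths and control information flow between its regions. The pipeline
implemented here is the standard seven-step procedure for this analysis:

1. **Extended network** — the seed (candidate) genes, their direct
   interaction partners from a scored edge table (combined score on the
   0–1000 scale, filtered at a confidence threshold), and every qualifying
   edge among the included nodes.
2. **Giant component** — the largest connected component, the object of
   all downstream analysis; small detached components are set aside.
3. **Node metrics** — for every node *v* of the giant component with *n*
   nodes: degree *K(v)*; normalized betweenness centrality

   *BC(v) = [ Σ_{s≠v≠t} σ_st(v) / σ_st ] / [ (n−1)(n−2)/2 ]*,

   where σ_st counts the geodesics between *s* and *t* and σ_st(v) those
   passing through *v* (Brandes' algorithm); and closeness centrality
   *CC(v)* = (r−1) / Σ_u d(v,u), the reciprocal of *v*'s mean geodesic
   distance within its r-node component. Network summaries: average
   degree ⟨K⟩ = 2E/N, mean shortest path length, diameter.
4. **Key nodes** — the top 10% (configurable) by degree and by BC, and
   their intersection: genes that are simultaneously hubs and bottlenecks.
5. **Backbone** — the induced subgraph on the top-k (default 15) BC
   nodes, the heavily used crossing points of the network.
6. **Shortest-path subnetwork** — the induced subgraph on the union of
   *all* geodesics between every pair of candidate genes.
7. **Validation** — resample seed subsets (default 80%, 100 replicates),
   rebuild the network, and record how often each backbone node returns
   to the replicate's top-k BC set.

Ties at every cutoff are included in full and all iteration is in
lexicographic node order, so every output file is byte-reproducible.

## Worked example

Real interactome snapshots are rarely archived with a study, so the
package ships generators for synthetic benchmarks with known ground
truth. A planted-bottleneck network joins two dense cliques through
bridge nodes whose betweenness is maximal by construction — the pipeline
must find them:

```python
from ppitopo import (
    generate_planted_bottleneck, emit_interaction_table, sample_seed_list,
    build_extended_network, giant_component, build_backbone, validate_backbone,
)

net, planted = generate_planted_bottleneck(clique_size=8, n_bridges=1, rng_seed=3)
table = emit_interaction_table(net, 400, 999, rng_seed=3)
seeds = sample_seed_list(net, net.n_nodes, rng_seed=3)

giant = giant_component(build_extended_network(seeds, table, min_score=400))
backbone = build_backbone(giant, k=1)
print(backbone.selected[0])         # ('B0001', 0.5333333333333333)
print(backbone.selected[0][0] in planted)   # True

report = validate_backbone(table, seeds, planted, seed_fraction=0.8,
                           n_replicates=50, k=1, rng_seed=7)
print(report.frequencies)           # {'B0001': 1.0}
```

The bridge node `B0001` is the top-betweenness node (its normalized BC,
0.533, means ~53% of all geodesic pair-flow crosses it), and it keeps its
top rank in 100% of 50 seed-resampled replicates — the backbone is robust
to perturbation of the input gene list.

The same stages run from the shell:

```sh
ppitopo simulate --bottleneck-cliques 8 --n-bridges 1 --rng-seed 3 --out sim/
ppitopo run sim/seeds.txt sim/interactions.tsv --min-score 400 \
        --backbone-k 1 --replicates 50 --out out/
# {"giant_edges": 58, "giant_nodes": 17, "top_betweenness_node": "B0001"}
```

`out/` then contains every intermediate artifact: `extended_network.sif`,
`giant_component.sif`, `node_metrics.tsv` (degree / betweenness /
closeness per node), key-node lists, `backbone.sif`,
`path_subnetwork.sif`, `validation.tsv` and a `summary.json`.

The packaged reference tables from a published oral-cancer PPI study are
available as inputs too: `oral_cancer_candidate_genes()` (the 208-symbol
candidate list) and `reported_key_nodes()` / `reported_rankings()` (its
published centrality tables). Re-ranking those rows reproduces the
study's headline readout — TP53 is the top hub (degree 113, BC
0.03881821) while TSPO is the top bottleneck (BC 0.04809981, degree 93),
and the best closeness score is 0.75409836 (EGFR).

## Not in scope

Live interaction-database or text-mining queries, GO/pathway enrichment,
and network visualisation/layout. Exact reproduction of the published
giant-component and backbone edge counts is not attempted: they depend on
an unversioned interactome snapshot that was never deposited.
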