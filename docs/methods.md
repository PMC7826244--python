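# Methods

## Graph model

All analysis operates on an undirected, unweighted, simple graph whose
nodes are canonical (uppercase) gene symbols. Interaction confidence
scores are consumed once, as an ingestion filter on the 0–1000
combined-score scale; they are never used as edge weights. This matches
how published disease-network centrality tables are produced: degree,
betweenness and closeness are unweighted-graph quantities, and treating
the score as a weight would change their meaning. Self-loops and
duplicate edge orientations — both common in database exports — are
dropped at construction with a logged count.

The *extended network* is the full induced subgraph on the seed genes and
their direct interaction partners: seed–seed, seed–neighbour **and**
neighbour–neighbour edges among the included nodes are all kept. The
one-hop expansion convention of interactive network tools behaves this
way, and the induced form is the stricter, reproducible definition (the
alternative — keeping only edges incident to a seed — discards exactly
the triangles that betweenness analysis is most sensitive to). Seeds with
no qualifying interaction remain as isolated nodes with a warning, so a
candidate list never silently shrinks.

## Centrality conventions

* **Betweenness** is computed with Brandes' dependency-accumulation
  algorithm (O(NE) for unweighted graphs), authored in this package
  because the bottleneck statistic is the pivot of the whole pipeline and
  must be verifiable: the test suite checks it to 1e-12 against an
  independent exhaustive-geodesic-enumeration oracle on hundreds of small
  random graphs, against the closed-form tree identity
  Σ_v BC_raw(v) = Σ_{s<t} (d(s,t) − 1), and against networkx. Endpoints
  are excluded; disconnected pairs contribute nothing. The normalized
  value divides by (n−1)(n−2)/2 — the undirected pair count of the
  analysed network — which is the convention behind published BC values
  of order 0.01–0.05 on ~200-node disease networks (raw values would be
  in the thousands).
* **Closeness** is the reciprocal of a node's mean geodesic distance
  *within its component*, CC(v) = (r−1)/Σ d(v,u); isolated nodes score 0.
  This is the convention of the common interactive analysers (not
  harmonic centrality, not the component-size-penalised variant), again
  chosen so values are comparable with published tables, where top
  closeness scores around 0.75 are typical.
* **mspl and diameter** are taken over connected unordered pairs only,
  because extended networks are routinely disconnected; an edgeless
  network reports both as 0 with a warning rather than failing.

Every ranking breaks ties lexicographically by symbol, and every cutoff
(top-k backbone, top-fraction key nodes) includes all nodes tied with the
cutoff value, recording the effective k. Determinism over exact-k: the
alternative — dropping an arbitrary subset of tied nodes — would make
outputs depend on iteration order.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `min_score` | 400 | combined-score ingestion threshold (0–1000); 400 is the customary "medium confidence" cut |
| `backbone_k` | 15 | backbone size: top-k nodes by normalized BC |
| `key_fraction` | 0.10 | key-node cutoff: top 10% by degree and by BC |
| `seed_fraction` | 0.8 | fraction of seeds retained per validation replicate |
| `n_replicates` | 100 | validation replicates |
| `rng_seed` | 0 | seed for all resampling |

The top-15 / top-10% cutoffs are the customary choices for backbone
extraction and key-node selection on networks of a few hundred nodes.
`key_fraction` is exposed rather than hard-coded because published
key-node counts under a nominal "10%" rule vary widely with how ties and
the two criteria are combined; the package takes no position and reports
whatever the configured fraction selects, ties included. Validation at
80% retention with 100 replicates is the standard jackknife-style
robustness convention: each replicate drops a random fifth of the seed
list, rebuilds everything from scratch, and asks whether each backbone
node regains a top-k betweenness rank. The validation metric is top-k
*membership*, not BC-value correlation — robustness of the ranking is
what the backbone claims.

## Synthetic benchmarks

Interactome snapshots underlying published disease networks are rarely
deposited, so correctness is established on generated inputs with known
structure instead.

* `generate_scale_free` is a preferential-attachment generator (seeded,
  clique-start: C(m+1,2) + m(n−m−1) edges) producing the hub-dominated
  degree distribution characteristic of PPI networks — a few very highly
  connected nodes among many sparsely connected ones. Defaults (208
  nodes, attachment 8, scores 400–999) put the synthetic giant component
  in the density regime of a literature-curated oral-cancer network:
  ~1630 edges, average degree ~15.7. It is written in-package because the
  commonly available preferential-attachment generators use a different
  (starless) initialisation and do not satisfy the exact edge-count
  formula above.
* `generate_planted_bottleneck` joins two cliques through a chain of
  bridge nodes. Every inter-clique geodesic crosses every bridge, so each
  bridge provably out-scores every clique node on raw betweenness — a
  ground truth the backbone and validation stages must recover. The
  recovery benchmark uses clique size 8 with one bridge, sampling 80% of
  nodes as seeds (matching the validation convention).

What the generators do **not** emulate: the modular/community structure
of real interactomes, degree-correlated confidence scores, study-bias in
edge coverage, and gene-symbol aliasing. Passing the recovery benchmarks
therefore shows the machinery is correct and robust to seed perturbation,
not that any particular biological network's published centrality values
would be reproduced — those depend on the exact interaction snapshot.

## Reference tables

The package ships, as plain-text inputs: the 208-symbol oral-cancer
candidate gene list from a published study (preserved verbatim — it
contains both `VEGF` and `VEGFA`, which are not merged, and loads to
exactly 208 unique symbols), the study's table of the ten nodes that are
simultaneously hubs and bottlenecks, and its top-15 rankings by degree,
closeness and betweenness. Re-ranking these rows through the package's
selection operations reproduces the published readout (TP53 as top hub,
TSPO as top bottleneck, EGFR as top closeness node) and anchors the
ranking conventions; the underlying network itself is not reconstructible
and its node/edge counts are documented, not asserted.

## Numerical and degenerate-input choices

* Betweenness on graphs with n < 3 is defined as 0 everywhere
  (no interior pairs exist).
* `build_backbone` clamps k > n to n with a warning rather than erroring;
  `select_key_nodes` rejects an empty metrics list.
* Validation replicates draw ⌈seed_fraction·n⌉ seeds without replacement
  from a NumPy `default_rng(rng_seed)`; with `seed_fraction = 1.0` every
  replicate is identical and the report is rng-independent by
  construction.
* All floating-point table output is fixed 8-decimal format; JSON output
  is key-sorted — reruns are byte-identical.

## Known limitations

* Exact reproduction of published centrality *values* requires the
  original interaction snapshot; only ranking behaviour on the published
  tables is checked.
* Betweenness is exact, not sampled; beyond ~10⁴ nodes an approximate
  variant would be needed (out of scope).
* The validation resamples the seed list only; edge-level (bootstrap)
  perturbation of the interaction table is not implemented.
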