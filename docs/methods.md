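# Methods

## The analysis

`ppinet` implements the standard seed-protein-to-backbone workflow used in
network-medicine studies of complex disease:

1. **Network construction.** A scored interaction table (the STRING export
   dialect: two protein identifiers, per-evidence-channel scores as raw
   integers 0–999, and a combined score) is filtered to a chosen channel
   set and confidence threshold. Channel scores are combined with the
   probabilistic-union rule: each selected channel score `s_c` is
   prior-corrected, `s'_c = max(0, (s_c − p)/(1 − p))`, and the combined
   score is `1 − Π_c (1 − s'_c)`. The default prior is `p = 0.041`, the
   conventional prior probability that a random protein pair interacts;
   the default threshold is 0.90, *inclusive*. The surviving edges form an
   undirected simple graph, and the analysis proceeds on its giant
   (largest connected) component.
2. **Topology metrics.** On the giant component: degree *k*, betweenness
   centrality BC (Brandes; endpoints excluded; fractional credit for tied
   shortest paths; normalised by `(N−1)(N−2)/2` so BC ∈ [0, 1]), closeness
   CC = `(N−1)/Σ_u d(v,u)`, eigenvector centrality EC scaled to max = 1,
   eccentricity with radius/diameter/center, and local clustering
   `2t/(k(k−1))`. Global summaries: N, E, ⟨k⟩ ± sample sd (n−1
   denominator), diameter, radius, center, mean shortest path length over
   unordered pairs (mspl), and the arithmetic mean of local clustering
   (acc), zero-valued low-degree nodes included.
3. **Backbone retrieval.** Hubs are the top fraction (default 10%) of the
   degree ranking, bottlenecks the top fraction of the BC ranking; the
   target count is `floor(0.10·N)`, minimum 1, and *every* node tied with
   the cutoff value is included — ties are never broken arbitrarily. The
   backbone is the union of the two sets with the subgraph it induces and
   a role flag (hub / bottleneck / both) per member.
4. **Second extension.** The backbone members are re-expanded by one
   interaction shell: all first neighbours reachable through table edges
   passing the same channel/threshold filter, plus all qualifying edges
   among the collected nodes. This replays the published procedure of
   re-querying the interaction database with the backbone as input, but
   from a supplied table, so it is reproducible offline.
5. **Backbone robustness.** Two backbones (e.g. with and without the
   coexpression channel) are compared by their common member set and by
   labeled-edge-set equality of the two induced subgraphs restricted to
   the common members. No common members makes the equality vacuous; the
   comparison record flags that case.
6. **Pathway annotation.** Gene sets (GMT) are intersected with the node
   set; only membership is reported, never enrichment statistics — the
   workflow this package reproduces reported membership counts only, and
   inventing an enrichment analysis would overstate it.

## Numerical choices

* **Eigenvector centrality** is computed by power iteration from the
  uniform vector with L1 renormalisation each step, stopping when the L1
  change between iterates is below `tol` (default 1e−10, `max_iter`
  10 000); non-convergence raises with the residual. The iteration matrix
  is `A + I`: the identity shift leaves the principal eigenvector
  unchanged while making the matrix primitive for any connected graph, so
  the iteration converges on bipartite graphs (a star oscillates with
  period 2 under plain `A`). Scores are reported scaled so the maximum
  is 1.
* **Betweenness normalisation** divides by the number of node pairs
  excluding the vertex itself, `(N−1)(N−2)/2`; this is the convention
  under which published per-node BC values for a ~111-node network lie in
  [0, 0.36].
* **Degree spread** uses the sample standard deviation (n−1). This is the
  convention that reproduces the published backbone summary
  (21.31 ± 9.78 over the 16 printed degrees; the n denominator gives
  9.47).
* **Mean BC of the published backbone table.** The table's printed
  average is 0.112282 ± 0.082026, but the mean of its own 16 printed BC
  values is 0.1112282 — and the printed sd matches the recomputed sd
  exactly, so the printed mean is a transposed-digit misprint. The
  package reports the recomputed value.
* **Edges are unweighted after filtering**; all distances are hop counts.
  Published distance summaries for such networks are integer-consistent
  (diameter 7, mspl 3.31), confirming hop-based convention.
* **Edge-count enrichment** is an explicit Erdős–Rényi null: the user
  supplies a background density `p̂`, and the Monte-Carlo draw samples the
  edge count `Binomial(C(n,2), p̂)` directly (that *is* the G(n, p) edge
  count law), with the add-one estimator `(1+k)/(n_random+1)` and its
  Monte-Carlo standard error. This deliberately does **not** reproduce
  the degree-conditioned enrichment p-values printed by interaction
  databases; the closed-form binomial tail is used as the test oracle.
* **Determinism.** Nodes are inserted and iterated in lexicographic
  order everywhere; giant-component ties go to the component containing
  the smallest label; the pipeline log carries no timestamps, so a fixed
  config + seed reproduces the output bundle byte for byte.

## The synthetic generator

`ppinet.synth` emulates a STRING-style export around designated seed
proteins with known ground truth, so every pipeline stage is testable
without downloads.

* **Topology.** Growth starts from a clique on the `n_seeds = 13` seed
  proteins. Planted hubs (`n_planted_hubs = 3`) enter next, attached to
  the entire seed clique (a protein interacting with the whole query
  module), and thereafter carry extra attachment mass
  `(degree + 10) × hub_boost` (default boost 10). Remaining nodes attach
  `m = 4` links each: the first preferentially by attachment mass, later
  links closing triads (copying a neighbour of an earlier target) with
  probability 0.9. Finally 450 closure rounds connect random open triads.
  One `numpy` Generator seeded by `rng_seed` drives the whole replicate.
* **Scores.** True edges draw experimental and database scores from
  Beta(45, 2) (mean ≈ 0.96; essentially every such edge passes the 0.90
  combined threshold on {experimental, database}). A fraction
  `coexpression_extra_density = 0.10` of true edges is instead supported
  only by a Beta(45, 2) coexpression score, so the with-coexpression
  channel setting recovers strictly more edges. Spurious non-edges
  (0.5·E of them) carry textmining/coexpression scores from Beta(2, 8)
  and never pass the threshold on any analysed channel set. All scores
  are quantised to the 1/1000 file resolution at generation time so the
  table round-trips exactly.
* **What the defaults produce** (measured over 50 development seeds):
  a connected 111-node graph with E ≈ 615, heavy-tailed degrees
  (max/mean ≈ 7.6), acc ≈ 0.75 and mspl ≈ 1.9, and the three planted
  hubs in the top three degree ranks in every seed examined. This is the
  intended high-clustering small-world regime, though denser and
  shorter-pathed than the published 111-node network (acc 0.672,
  mspl 3.31): the seed clique plus strongly boosted hubs compress path
  lengths. The generator is a test harness, not a fitted model of any
  real subnetwork — passing recovery tests shows the pipeline finds
  planted structure under realistic score noise, not that it would
  reproduce any particular database snapshot.
* **What it does not emulate:** correlated evidence channels, study-bias
  (degree-dependent textmining coverage), protein-family substructure,
  and database-version drift.

## Problem sizes used in validation

The worked example is the published 16-row backbone table (exact
arithmetic, instantaneous). Synthetic validation uses the default
conditions above: 100 replicates for planted-hub recovery, 20 for channel
monotonicity, 200 random ≤7-node graphs plus 30–100-node graphs for the
centrality-oracle comparisons, and a double pipeline run for bytewise
determinism. The full suite runs in well under a minute on one CPU.

## Known limitations

* Exact (non-sampled) betweenness only — fine at desk scale (hundreds of
  nodes), not for proteome-scale graphs.
* Centralities are unweighted and undirected by design; confidence scores
  are used only for filtering, never as edge weights.
* The second extension can only re-expand within the supplied table; it
  cannot reproduce a live database query that would bring in proteins
  absent from the table.
* `compare_backbones` tests labeled-edge-set equality, not isomorphism.
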