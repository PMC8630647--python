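# Methods

`follinet` analyzes directed signaling networks distilled from curated
literature tables of molecular interactions — here, the interaction
database underlying in vitro folliculogenesis (ivF), where nodes are
hormones, receptors, intracellular signaling molecules and follicular
events, and each directed edge is one curated statement ("FSH activates
FSHR in rodent, PMID ...").  This note records the models, conventions and
numerical choices the package fixes, and what its tests do and do not
demonstrate.

## Network construction

A curated table is collapsed into a **simple directed graph**: one edge per
ordered (source, target) pair, annotation lists (interaction labels,
species, PMIDs) merged across contributing records, self-loops dropped.
Two conventions drive this: the normalized betweenness definition used
downstream is valid only on graphs without parallel edges, and a single
link count must describe the network.  Node identity is the canonicalized
name string (trimmed, internal whitespace collapsed, case preserved); no
synonym resolution is attempted, because merging biological aliases is a
curation act, not a computation.

## Distance conventions

Degree-based quantities (degrees, the hub rule, the in/out ratio) respect
edge direction.  Distance-based quantities — components, characteristic
path length, mean neighbor count, clustering, closeness, betweenness, and
the default bottleneck trees — use the **undirected projection**.  A
layered source-to-sink network is never strongly connected, so directed
distances would leave most node pairs undefined; one connected component
and nonzero closeness for every node are only coherent under undirected
distances.  Directed variants are available (`directed=True`,
`--directed`) for sensitivity analysis.

## Centralities and the bottleneck score

Closeness is the reciprocal of the mean shortest-path length to reachable
nodes, 0 for isolated nodes.  Betweenness sums, over unordered pairs
{s, t} with s ≠ n ≠ t, the fraction of shortest s–t paths through n, and
is normalized by (N−1)(N−2)/2 with N the size of n's connected component,
so both measures live in [0, 1].  Both are delegated to networkx
(betweenness is computed per component so the normalization uses component
size).

The **bottleneck score** BN(v) is implemented in-house.  For every root s
one shortest-path tree T_s is grown by breadth-first search; v earns a
point from s when more than |V(T_s)|/4 of the tree paths from s pass
through v, and BN(v) sums the points over all roots.  The number of tree
paths through v equals the size of the subtree rooted at v.  Two
conventions are fixed and exposed:

* *Tree choice.* Shortest-path trees are not unique.  BFS visits neighbors
  in lexicographic node order and the first discoverer becomes the parent,
  making every score deterministic and label-covariant.  The test suite
  also runs a reverse-lexicographic variant to document (not hide) the
  sensitivity of scores to the tree choice.
* *Endpoint counting.* By default the path's own endpoint counts as
  "passing through" its terminal vertex (the subtree-size convention), so
  on a single edge a–b each node scores 1 (the one path from the opposite
  root, 1 > 2/4).  The strict-interior reading
  (`include_endpoint=False`) is also implemented; there the same graph
  scores 0.

## Controllers

A **hub** is a node whose total degree strictly exceeds μ + σ, with μ and
σ the mean and *population* (divide-by-n) standard deviation of total
degree over all nodes; with all degrees equal no node qualifies.
**Bottlenecks** are the top-k nodes by BN score, k defaulting to the hub
count (the ranking is a top-N selection and the two controller families
are then commensurate); ties at the cutoff break by higher degree, then
name.  The **hub.BN** intersection is the controller set proper, and
shares of the network are reported as percentages rounded to one decimal
(38 hubs of 641 nodes → 5.9%; a 46-node union → 7.2%).

## Stratification

The in/out degree ratio DR_IO = 100·γ_IN/(γ_IN+γ_OUT) is the percentage of
a node's links that are incoming.  (The ratio γ_IN/γ_OUT·100 sometimes
quoted for this quantity is unbounded and cannot be laid against 0–100
layer cutoffs; the in-fraction is the reading under which pure sources map
to 0, pure sinks to 100, and the published cutoffs are meaningful.)
Layers: input DR_IO ∈ [0, 36), processing [36, 68), output [68, 100] —
integer band edges generalized to half-open real intervals, declared
rather than inferred since boundary treatment is otherwise unspecified.
The bands are deliberately asymmetric (the published ones are), so edge
reversal maps DR_IO to 100−DR_IO exactly and sends every output-layer node
into the input layer, but values in (64, 68) land in processing rather
than input.  Isolated nodes have no defined ratio and are excluded with a
log message.

## Attack experiments

Each targeted cycle removes ⌈0.025·n_current⌉ nodes by descending total
degree (ties: higher BN score, then name); the random control removes the
same count uniformly, from a mandatory seed.  After each cycle the
topology is summarized and the giant fraction (largest weak component /
original node count) recorded.  **Collapse** is a defined artifact, not a
reconstruction of any published rule: giant fraction < 0.5, or the
post-attack total-degree distribution failing a power-law fit (r² < 0.5,
or fewer than three distinct positive degrees — "unfittable").  Both
thresholds are configurable.  Requesting a cycle whose removal count would
round to zero (fraction·n < 1) is an error rather than a silent no-op.

## Power-law fits

`powerlaw_fit` regresses log₁₀(frequency) on log₁₀(degree) over distinct
positive degrees by ordinary least squares — the network-analysis
convention, chosen to reproduce the behavior of the tooling the reference
numbers come from — reporting the slope Γ, Pearson r, and r².  It is *not*
a maximum-likelihood tail estimator and its Γ is not comparable to ML
exponents.  A constant frequency vector has slope 0 and r reported as 0;
fewer than three distinct positive degrees is an error.

## Kernel density estimation and subpopulations

The estimator is a Gaussian product kernel with an independent bandwidth
per dimension, h_i = sd_i · (4/((d+2)n))^(1/(d+4)) (Silverman's rule),
evaluated on a ≥128-point-per-axis grid spanning the data ± 3 bandwidths
(truncation keeps the quadrature integral within 1% of 1; the suite
asserts 1 ± 0.02).  Dimensions with zero spread get a bandwidth floor of
1e-6 × range (or 1e-6 absolute).  2D input — node degree × BN score, which
live on incommensurate scales — is z-standardized before smoothing and
mode locations are mapped back.  The evaluation is written directly in
numpy because the required bandwidth matrix is diagonal and per-dimension;
the suite cross-checks it against scipy's covariance-factor KDE with a
matched bandwidth.

Subpopulations are density modes: grid cells are flooded in order of
decreasing density (watershed), each new summit founds a basin, and when
two basins meet at a saddle the lower-prominence one is merged into the
higher if saddle ≥ 0.5 × (lower peak) (`merge_ratio`).  This persistence
step is what separates genuine subpopulations from sampling wiggles: at
Silverman bandwidths a single 40-point Gaussian cluster routinely shows
2–3 spurious local maxima whose saddles sit at >0.8 of their peaks, while
clusters separated by ≥8σ meet at saddles below 0.05 of their peaks.
Every point is assigned by discrete gradient ascent from its nearest grid
cell to a surviving mode — unless its own kernel density falls below
`density_quantile` (default 0.05) × the peak grid density, in which case
it is reported as *isolated*.  The isolation level is relative to the peak
rather than a per-point quantile, which would by construction always
isolate the lowest tail even of a single clean cluster.

## Synthetic data generator

The curated database exists only as journal supplementary material, so the
generator is a first-class module producing databases with the statistical
structure the analysis assumes, plus ground truth.  Defaults are the study
conditions: 641 nodes, 2086 links, layer proportions 0.30/0.25/0.45
(input/processing/output), species labels drawn from the published
mammal-model incidence (Rodent 39.17% ... Canine 0.16%), interaction
labels from {activates, inhibits, induces, binds}, synthetic 8-digit
PMIDs, opaque zero-padded node names.

The skeleton is grown by **saturating preferential attachment**: a growth
tree in which each new node attaches to an existing node with probability
∝ min(degree, 40)^1.5, densified with chords whose endpoints follow the
same weight, to the exact edge target.  The saturation/exponent pair is a
structural choice, not a fit to any published statistic: plain linear
preferential attachment at this density spreads edges too evenly — its
networks survive three cycles of 2.5% hub removal essentially intact and
show a much steeper degree-frequency slope than curated interaction
networks, where a minority of heavily studied molecules (the FSH/PI3K tier)
carries most documented edges.  The saturating weight concentrates edge
mass on a core of comparably connected hubs while the periphery stays
tree-like, jointly yielding (checked over 20 seeds): frequency-slope fits
with r² ≈ 0.75–0.84 and Γ ≈ −1.2, a hub minority of ~5–6% of nodes,
fragmentation under two to three targeted 2.5% cycles, and insensitivity
to matched random removal.

Edge directions implement the layer ground truth: an edge {u, v} is
oriented u→v with probability ∝ emit(u)·(1−emit(v)), where emit is 0.9 for
input-layer, 0.5 for processing, 0.1 for output-layer nodes.  Input nodes
therefore emit the large majority of their links, making degree-ratio
stratification recoverable (~72–89% of planted input nodes per seed).

What the generator does **not** emulate: biological node identities,
the curated network's clustering coefficient (≈0.076) and characteristic
path length (≈5.656) — the synthetic core is denser and shorter-ranged
(clustering ≈0.25–0.3, path length ≈2.7–3.2) — or any literature-coverage
bias structure beyond the species marginals.  Green tests on synthetic
data therefore certify the *algorithms* (oracle-exact centralities,
recoverable planted structure, qualitative attack asymmetry), not the
real network's metric values, which require the original curated table.

## Pipeline and reproducibility

`run_pipeline` executes load/generate → topology → centralities →
controllers → stratification → targeted + matched random attack → KDE,
writing TSV/JSON per stage and a manifest with the config, a config hash,
derived per-stage seeds, and a SHA-256 per output.  All randomness derives
from one root seed by stable integer derivation (< 2³¹); floats in
reports are fixed to 6 significant digits; stage durations go to the log,
never into hashed files — so identical configs produce byte-identical
bundles, which the suite asserts at the default study size.

## Problem sizes used in the tests

The suite validates centralities oracle-exactly on 200 random connected
graphs of ≤ 10 nodes (exhaustive path enumeration is exact there), runs
attack comparisons at 400–500 nodes and generator/stratification checks at
the full 641-node default, and uses 40-point-per-cluster KDE simulations —
sizes at which every stochastic assertion was verified to hold with margin
across 20 seeds while the whole suite completes in a few minutes.

## Known limitations

* Published metric values that depend on the original curated table
  (clustering 0.076, path length 5.656, mean neighbors 5.042, the exact
  38/38/30 controller counts) can only be checked against that table; the
  package reports its own computed values for any input it is given.
* The OLS log-log fit is a conventional, biased estimator of power-law
  exponents; use it for comparability, not inference.
* BN scores depend on the (deterministic) tree-construction convention;
  alternative valid trees can change individual scores.
* KDE subpopulation counts depend on bandwidth; defaults are rules of
  thumb, and both bandwidth and the merge/isolation thresholds are
  configuration, not science.
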