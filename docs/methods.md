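# Methods

## From sequences to networks

The unit of input is a *bout*: one continuous singing sequence of phrase
labels. Labels are opaque strings; numeric-looking IDs get no special
treatment. Within each bout, runs of immediately repeated phrases are first
collapsed to a single token (`a a b` → `a b`), because the global measures
used here are defined for simple graphs without self-loops; collapsing
(rather than discarding the pair) keeps the `a → b` transition. Every
adjacent ordered pair in the collapsed bout then contributes one observed
transition. Transitions never span bout boundaries: bouts are separated by
recording breaks, and sequence beginnings/ends are exactly what the Margin
motif class captures. Bout granularity is the user's choice via the input
file — a corpus may be seven long sessions or many short pause-delimited
bouts, and the tool imposes neither.

The song directed network (SDN) has one node per phrase type observed
anywhere in the corpus (phrases seen only in single-phrase bouts are
isolated nodes) and one arc per observed ordered transition; arcs carry the
observed transition count, which the network topology ignores but the
occurrence-vs-degree analysis uses. The song undirected network (SUN) is
the direction-forgetting projection: reversible transitions collapse to one
edge.

## Global measures

* **Average path length L** — the mean shortest-path hop count over ordered
  node pairs (u, v), u ≠ v, restricted to pairs where v is reachable from u
  (undirected reachability for the SUN, directed for the SDN). Unreachable
  pairs are *excluded* from the average rather than assigned ∞ or n; this
  keeps L finite on digraphs that are not strongly connected and on
  disconnected graphs, and reports flag the convention. L is undefined
  (error) on edgeless networks.
* **Clustering coefficient C** — C_i = E_i / (k_i(k_i−1)/2) with E_i the
  number of edges among node i's k_i neighbours; C_i := 0 when k_i < 2, and
  such nodes are included in the average over all n nodes (the only finite
  choice consistent with averaging over every phrase). Defined for
  undirected networks only; passing a digraph is a type error.
* **Degree distribution P(k)** — the fraction of nodes with degree k. For a
  digraph the default degree is the total (in+out) degree, so that a
  digraph's mean degree equals 2·arcs/n; in- and out-degree histograms are
  also available.
* **Small-world-ness S** = (C/C_rand) / (L/L_rand), with C_rand and L_rand
  the means of a matched random-network ensemble; S > 1 indicates
  small-world structure. All four inputs must be positive.
* **Z-scores** — (observed − ensemble mean)/ensemble SD, with SD from the
  null ensemble (ddof = 1); an SD of exactly 0 is reported as a flagged
  degenerate case rather than a Z.

Internally all measures are kept at full float precision; any 2-d.p.
rounding happens only in reports.

## Transition motifs

Each SDN node is classified from its (in-degree, out-degree) pair: Margin
if either degree is 0 (this takes precedence, so an isolated node or a pure
source/sink is Margin regardless of the other degree — precedence is what
makes the five classes exclusive); otherwise One-way (1,1), Bottleneck
(≥2,1), Branch (1,≥2), Hourglass (≥2,≥2). One-way and Bottleneck are
deterministic (the successor is forced), Branch and Hourglass
non-deterministic.

Profiles are compared to a null ensemble with per-class Z-scores on
*counts* and a chi-square test of observed counts against expected counts
(null mean proportions × n), 4 degrees of freedom over the five classes.
Classes with zero expected count are pooled into the smallest non-zero
expected class before the test, reducing the degrees of freedom; the
pooling is recorded in the result and warned about. A null class with zero
SD and a differing observed count yields an infinite Z with a warning.

## Null models

Random undirected networks (RUN) and random directed networks (RDN) are
matched to the observed network's node count and average degree. The model
is Erdős–Rényi-style with an exact-count constraint: each unordered pair
(RUN) or ordered pair (RDN) independently receives an edge with probability
p = target/#pairs, and the draw is kept only if its edge count equals the
target exactly, otherwise redrawn. Matching "the same average degree" is
implemented as this exact count match — equivalent at fixed n and free of
float comparisons. The default arc budget when matching a digraph at a
stated mean total degree ⟨k⟩ is round(n·⟨k⟩/2).

The sampler exploits that the edge count of an independent-pair draw is
Binomial(#pairs, p) and that, conditional on the count, the edge set is a
uniform subset: it redraws the binomial count until it hits the target
(this is the rejection loop; attempts are capped, default 10⁶, with a
convergence error beyond that) and then places exactly the target number of
edges uniformly at random. This is distributionally identical to
generate-then-reject on whole graphs and orders of magnitude faster. For
the RDN, independent per-ordered-pair arcs are one concrete reading of
placing in-, out- and bi-directional edges with equal probability; under it
the in- and out-degrees are asymptotically Poisson(arcs/n), which provides
the closed-form cross-check used in the tests (e.g. the expected Hourglass
fraction is P(Pois ≥ 2)²).

Ensemble summaries (default 1,000 replicates) report per-measure mean, SD
and the observed value's Z; they are deterministic for a fixed seed, with
per-replicate seeds derived from the master seed.

**Shuffled corpora** perform a fixed number of position switches (default
1,000) of uniformly chosen global token-position pairs, chosen with
replacement across iterations; a self-swap counts as one switch. Bout
lengths and the per-label token counts are preserved exactly while
transition contexts are destroyed. The swap count is a parameter rather
than an asserted mixing guarantee. The **occurrence-vs-degree** table pairs
each phrase's raw token frequency (repeats not collapsed) with its share of
total SDN degree; under random transition placement common phrases gain
proportionally more connections, so stereotyped popular phrases fall below
the shuffled trend.

## Robustness analyses

**Rarefaction** rebuilds the networks on temporal prefixes of the corpus
(the first s tokens for s = step, 2·step, …, total), matching a cumulative
sampling design; the final point is bitwise the full-corpus analysis. A
random-subsampling mode is available for comparison. Prefixes whose
networks are edgeless keep their row with `None` markers for the undefined
measures instead of being dropped. Repertoire size keeps growing with
sample size while L, C and the motif proportions stabilise much earlier —
the reason network measures are usable on realistically sized recordings.

**Noise perturbation** imitates phrase misclassification: exactly
round(rate·N) token positions (round-half-to-even, for a deterministic and
unbiased count) are chosen uniformly without replacement, and each chosen
token is replaced by a uniform draw from the observed repertoire
*excluding* its current label — so the requested rate equals the realised
misclassification rate. Replacements reuse existing categories because
misclassification confuses known types; a novel-label mode is not the
default. A single-label repertoire cannot be perturbed (no alternative
exists) and errors. The sweep runs a configurable number of replicates per
rate (default 100) with derived seeds and reports each measure's mean and
SD; at rate 0 the SDs are exactly 0. Whether noise inflates or deflates C
depends on density: when the repertoire is large relative to the token
count (the realistic regime), noise scatters edges thinly and both L and C
fall past ~10% noise; on small dense repertoires added random edges can
raise C instead.

## Synthetic ground truth

`planted_graph` builds a Watts–Strogatz-style ring lattice (n nodes, k even
nearest neighbours, rewiring probability beta). At beta = 0 the lattice has
closed-form clustering 3(k−2)/(4(k−1)) and is vertex-transitive; beta ≈ 0.1
is the small-world regime the pipeline must detect; beta = 1 approaches an
Erdős–Rényi graph with C ≈ k/(n−1). The directed variant assigns both
directions to every lattice edge and then rewires arcs independently
(keeping the source, drawing a fresh non-duplicate target).

`random_walk_song` emits tokens by a uniform random walk on the planted
digraph's out-neighbours with a teleport probability (restart). A teleport
models a bout ending and a new one beginning, so it inserts a bout boundary
rather than a spurious transition; dead ends teleport too (or error, if
restart = 0, naming the node). On top of the teleport boundaries the token
stream is split into a scheduled number of contiguous chunks, so the
requested bout count is a minimum. Because teleports never create arcs, a
sufficiently long walk on a strongly connected planted digraph
reconstructs the planted arc set exactly — the pipeline's end-to-end
recovery check.

What the generator does *not* emulate: repeat-run length statistics of real
phrases (repeats are collapsed anyway), heavy-tailed phrase usage (walk
occupancy on a near-regular graph is near-uniform, unlike real hub
phrases), and any acoustic or segmentation error beyond the label-level
noise model. Passing tests therefore demonstrate correctness of the
measures and the detection machinery on known structure, not that any
particular real species is small-world.

## Problem sizes and numerical choices

The test suite and the acceptance script use the ensemble sizes the
analysis is designed around (1,000 null replicates at up to 182 nodes),
which complete in seconds thanks to the binomial-count rejection sampler
and sparse-BFS path lengths (scipy `csgraph` on the adjacency structure).
Synthetic corpora in tests use 25–150 phrase types and 400–10,000 tokens —
the same order as real single-bird recordings. Determinism is guaranteed
everywhere a seed is accepted: ensembles, shuffles, perturbations, walks
and full reports (modulo the report timestamp). Replicate SDs computed over
identical values are clamped to exactly 0 to honour the rate-0 invariant
despite float round-off in the mean.

## Known limitations

* Binary topology only: transition probabilities are deliberately not
  modelled (that is the point of the approach — presence/absence needs far
  smaller samples than a Markov transition matrix), so the networks cannot
  distinguish a rare transition from a frequent one except in the
  occurrence-vs-degree view.
* Network measures are uninformative on very small repertoires (tens of
  nodes or fewer); the tool computes them regardless.
* The RDN sampler is one reading of equal-probability directed edge
  placement; other readings (e.g. explicitly sampling bi-directional pairs)
  would match the same mean degree but differ slightly in motif mix.
* The L convention (unreachable pairs excluded) is a choice; comparing L
  values across tools requires checking their convention for disconnected
  or weakly connected graphs.
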