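# Methods

## The density model

The clusterer treats an interaction network as a simple undirected graph
and asks, node by node, whether the neighbourhood is denser than chance.
The null model is Bernoulli: each potential edge between two neighbours of
a node exists independently with probability *p*. Because interactomes are
clustered (two partners of the same protein are more likely to interact
than a random pair), *p* is set to the **global clustering coefficient** of
the input graph — 3·(#triangles) / (#connected triples) — rather than to
the raw edge density. *p* is recomputed for every analysed graph,
including every noise replicate, since adding edges changes the null; a
flag (`--edge-prob` / `ADHOC(edge_prob=...)`) overrides it for controlled
experiments.

For a node of degree *d*, with *D = d(d−1)/2* possible neighbour–neighbour
edges, the threshold edge count *C\** is the smallest *C* with

P(X ≥ C) ≤ p^(k(k−1)/2),  X ~ Binomial(D, p),

and MinCC = *C\*/D*. The right-hand side is the chance probability of a
complete *k*-clique, with *k* any real > 1 (the exponent *k(k−1)/2* is
well defined for non-integer *k*). A node is a *density node* when its
neighbourhood edge count reaches *C\** — the implementation compares
integer edge counts, which is exact, rather than floating coefficient
ratios. Feasibility has a closed form: since the best case *C = D* has
tail *p^D*, a degree can host a density node iff *D ≥ k(k−1)/2*; in
particular degrees 0–1 never can, and their local clustering coefficient
is defined as 0.

Numerical choices. Binomial tails use the exact survival function (the
regularised incomplete beta), never a normal approximation: the comparison
involves very small probabilities and an approximation error could shift
*C\** by one, which flips node classifications. The comparison is
inclusive (a tie counts as "as dense as the clique") and is guarded with a
relative tolerance of 1e-9, because exact ties do occur — at *d* = 3,
*k* = 3 both sides equal *p*³ — and last-ulp differences between tail
evaluations must not decide them. *C\** is found by binary search on the
monotone tail and memoised per (d, k, p); degrees repeat heavily in
scale-free graphs, so this matters on real inputs. *p* = 1 (complete
graph) degenerates to *C\** = 0; *p* = 0 (triangle-free graph) means no
neighbourhood can ever beat the null, so no clusters form and every node
is interspersed — the model's verdict, not an error. A graph with no
connected triples at all has an undefined coefficient and is rejected
unless *p* is supplied.

A property worth knowing: MinCC decreases with degree overall, but
because *C\** is an integer the ratio *C\*/D* can tick **up** by less than
1/*D* between consecutive degrees. Tests assert monotonicity up to this
quantisation bound, not strictly.

## Cluster assembly

For one density level *k*:

1. density nodes are identified as above;
2. cluster **cores** are the connected components of the subgraph induced
   on density nodes — paths through non-density nodes do *not* merge
   cores;
3. each density node's **density region** is its neighbours minus those
   with no edge to any other neighbour; every non-density node inside at
   least one region becomes a **border node** of each such density node's
   cluster (region membership, not mere adjacency, is the attachment
   condition — this reconciles the region definition with attachment "to
   directly connected density nodes");
4. **affiliated nodes** — unassigned nodes whose entire neighbourhood
   lies inside one cluster's member set — are attached, to every such
   cluster when the neighbourhood sits in an overlap. Attachment is
   iterated to a fixed point against the growing member sets. A
   structural consequence of the symmetric membership test is that the
   fixed point is reached after one parallel pass (a neighbour's
   attachment always presupposes this node's own membership), so the
   result is provably independent of node processing order; the iteration
   is kept as a guard.
5. the rest is **interspersed** and forms the inter-module layer.

Node classes are mutually exclusive with priority density > border >
affiliated > interspersed. Only border and affiliated nodes can belong to
several clusters; density nodes belong to exactly one. Cluster ids are
assigned by sorting cores on their lexicographically smallest member, so
output is reproducible byte for byte. No minimum cluster size is imposed
by default — small modules (size 4–5) are biologically meaningful — but
`min_size` dissolves smaller clusters into the inter-module layer when
asked.

Defaults: *k* = 3 for single runs (density of a node's neighbourhood
comparable to clique-size-4 methods), hierarchy schedule (3, 3.5, 5),
sweep step 0.5, hub degree threshold 10 (strict >).

## Hierarchy

Raising *k* raises every degree's threshold, so the density-node set
shrinks monotonically and cores at a higher level always sit inside a
lower level's clusters. Levels are computed as independent global runs —
not by re-clustering inside parents — which keeps *p* consistent across
levels and is equivalent for cores by the monotonicity argument. Each
child cluster is linked to the parent containing its core; full member
sets are *expected* to nest once border/affiliated attachment is added,
but that is not a theorem of the model, so the member-nesting fraction is
reported and core-straddling children (possible only under a min-size
filter or an overridden *p*) are recorded as violations rather than
hidden. Same-level overlaps are exported as a weighted cluster graph
(node size = member count, edge weight = shared members).

## Evaluation statistics

* **Enrichment**: hypergeometric upper tail with N = nodes of the
  analysed graph (the "whole network", not the genome), n = group size,
  M/m = term counts in background/group. Bonferroni multiplier = number
  of distinct terms carried by at least one group member (per group, per
  category); corrected p capped at 1 and reported as −log₁₀. Per-cluster
  summaries use the best (most significant) term, ties broken by term id;
  a flag switches to averaging over all tested terms. Clusters with no
  annotated member contribute 0.
* **Lethality**: binomial upper tail P(X ≥ k_lethal) with n = group
  size; the background lethal probability defaults to the lethal fraction
  among graph nodes with *known* status (unknowns excluded from both
  numerator and denominator), overridable.
* **Betweenness**: unnormalised shortest-path betweenness (sum over pairs
  of geodesic fractions), disconnected pairs contributing 0.
* **Hubs**: degree strictly greater than the threshold; module hubs are
  hubs inside ≥ 1 cluster, inter-module hubs are hubs in the inter-module
  layer. Group comparisons report mean ± sd (sample sd, ddof = 1; 0 for
  singleton groups) of intra-group hub–hub interaction counts and local
  clustering coefficients, plus two-sided two-sample Kolmogorov–Smirnov
  tests on the degree and betweenness distributions. The KS routine is
  delegated to scipy.
* **Function prediction**: a cluster whose best biological-process term
  exceeds a −log₁₀ p threshold (strictly) donates that term to every
  member lacking any annotation in the category. The conventional cutoff
  of 10 presumes a ~2800-protein background; scaled-down benchmarks need
  a proportionally smaller cutoff (the acceptance script uses 5 on its
  110-node benchmark).

## Noise protocol

Robustness is probed by adding round(f·|E|) edges, f ∈ {5%…25%}, sampled
uniformly without replacement from currently unconnected non-self pairs —
never removing or duplicating edges — then re-clustering with *p*
recomputed per replicate. Replicate RNG streams are spawned from the
master seed keyed by (fraction index, replicate index), so any subset of
the table reproduces bit-exactly. Dense graphs switch to exact non-edge
enumeration instead of rejection sampling. The fraction-0 row is the
single noiseless baseline.

## Synthetic benchmarks

The planted-module generator wires dense Bernoulli blocks (default: three
blocks of 10 at p_intra = 0.9), optional shared nodes between named
blocks, optional hubs (in-module or between-modules placement), and a
sparse background component (default: 80 nodes at p = 0.10). Background
edges only ever involve background nodes: a direct random edge between two
density nodes of different blocks would merge their cores by construction
of step 2 and destroy the planted truth the generator exists to provide.
The background's role is statistical as well as decorative — its open
triples pull the global clustering coefficient down to ~0.3, the range
observed in real interactomes. Without it the coefficient approaches
p_intra and the null absorbs the blocks: planted modules stop being
significantly denser than chance and recovery becomes seed-dependent.
This is a genuine property of the threshold model worth knowing when
interpreting graphs that are dense everywhere.

The nested generator plants a two-scale truth: parents consist of two
child cliques joined only through designated linker nodes (complete
bipartite wiring between sibling linker sets). Linker neighbourhoods span
both children, so they clear the permissive k = 3 threshold — fusing the
children into one parent cluster — but fail the stringent k = 5 one,
splitting the parent along the planted seam.

The annotation generator gives each module a dominant term at a stated
purity, leaves a stated fraction of members unannotated, and lets
background nodes draw from module terms plus an equal pool of
background-only terms, so module terms occur in the background at a basal
rate well below their in-module frequency.

What these fixtures do *not* emulate: power-law degree distributions,
duplication-divergence growth, correlated false negatives, weighted or
directed edges. Passing tests therefore demonstrate correctness of the
algorithmic contracts and qualitative behaviours (recovery, nesting,
overlap handling, robustness trends) — not performance guarantees on any
particular real interactome.

The frozen 21-node / 36-edge demonstration network was constructed by
hand — three dense blocks (K5, two K4), one pendant-pair attachment per
block, and a five-node connector path — and verified analytically: with
its own global clustering coefficient (63/102) at k = 3 it resolves into
exactly 3 clusters and 5 interspersed nodes.

## Problem sizes

Tests and the acceptance script run on graphs of tens to a few hundred
nodes, with hundreds of randomised instances for property checks and 30
replicates per noise fraction — sizes at which exhaustive oracles
(triple/path enumeration, linear threshold scans) remain exact and the
whole suite completes in seconds. The implementation itself is routinely
run on multi-thousand-node interactomes; memoised thresholds and a single
triangle count per run keep that in minutes on one CPU.

## Known limitations

* Unweighted, undirected graphs only; confidence scores are ignored by
  design.
* The Bernoulli null uses one global *p*; degree-correlated nulls
  (configuration model) are out of scope.
* Member-set nesting across levels is empirical, not guaranteed.
* Annotations are flat term assignments (GO-Slim style); no DAG
  propagation, and Bonferroni is the only correction offered.
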