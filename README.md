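# adhocnet

Density-based hierarchical and overlapping clustering of protein–protein
interaction (PPI) networks.

PPI networks are noisy, scale-free graphs in which functional modules —
complexes and pathways — appear as locally dense neighbourhoods. Classical
density clustering applies one density cutoff to every node, which fails on
scale-free degree distributions: a degree-2 protein reaches clustering
coefficient 1.0 trivially, while a degree-50 hub essentially never does.
`adhocnet` implements a **degree-adaptive threshold**: a node of degree *d*
is accepted as a *density node* only when its neighbourhood is at least as
dense as a *k*-clique would be under a Bernoulli null model. Modules are
then assembled from density nodes and their surroundings, allowing modules
to **overlap** and, by raising *k*, to resolve into a **nested hierarchy**
— like the zoom of a lens.

## The model

Let *p* be the network's global clustering coefficient
(3·triangles / connected triples), the probability of observing an edge
between two neighbours of a common node by chance. For a node of degree
*d* there are *D = d(d−1)/2* possible edges among its neighbours. The
minimum clustering coefficient MinCC(d, k) is *C\*/D*, where *C\** is the
smallest edge count satisfying

    P(X ≥ C*) ≤ p^(k(k−1)/2),   X ~ Binomial(D, p)

i.e. observing *C\** neighbourhood edges by chance is no more likely than
observing all edges of a *k*-clique by chance. *k* > 1 may be any real
number, so density can be tuned continuously. Degrees with
*D < k(k−1)/2* can never qualify. Given the density nodes, every node
receives exactly one of four classes and clusters follow:

1. **density** — local clustering coefficient ≥ MinCC(degree, k);
   directly connected density nodes seed the same cluster;
2. **border** — inside the *density region* of ≥ 1 density node (its
   neighbours, minus neighbours with no edge to any other neighbour);
   joins every such density node's cluster, creating overlaps;
3. **affiliated** — all edges lead into a single cluster's member set
   (attachment iterated to a fixed point);
4. **interspersed** — everything else: the *inter-module layer*.

Companion statistics reproduce a full evaluation protocol: cluster-wise
hypergeometric annotation enrichment with Bonferroni correction, binomial
lethality enrichment, unnormalised betweenness, hub partitioning
(degree > 10) into module vs inter-module hubs, module-based function
prediction for unannotated proteins, and a seeded random-edge-addition
robustness experiment.

## Worked example

Generate a benchmark network with three planted 10-node modules over a
sparse 80-node background, cluster it, and score it:

```sh
$ adhoc simulate --seed 7 --out edges.tsv --truth truth.tsv --annotations go.tsv
110 nodes, 435 edges -> edges.tsv
$ adhoc cluster --edges edges.tsv --k 3 --out clusters.tsv
3 clusters, 80 inter-module nodes -> clusters.tsv
$ adhoc hierarchy --edges edges.tsv --ks 3,3.5,5 --out hierarchy.json
3 levels, 9 clusters, member nesting 1.000 -> hierarchy.json
$ adhoc evaluate --edges edges.tsv --go biological_process go.tsv --out report.json
report -> report.json
```

The three planted modules are recovered exactly (`clusters.tsv` lists one
row per cluster membership with the node's class); the 80 background nodes
land in the inter-module layer, a discard rate of 72.7%. `report.json`
shows the edge-probability null actually used (p = 0.305, the graph's
global clustering coefficient) and a mean best-term enrichment of
−log₁₀ p = 6.49 over the three clusters against the planted annotations.
The hierarchy run confirms every cluster found at k = 3.5 and 5 sits
inside a k = 3 cluster.

The same thing in Python, estimator-style:

```python
import networkx as nx
from adhocnet import ADHOC, read_edge_list

graph = read_edge_list("edges.tsv")
model = ADHOC(k=3).fit(graph)
print(len(model.clusters_), model.p_)     # 3  0.305...
print(model.node_classes_["M0N00"].name)  # DENSITY
```

Other subcommands: `adhoc hubs` (module vs inter-module hub partition with
Kolmogorov–Smirnov comparisons), `adhoc robustness` (noise table,
mean ± sd over seeded replicates). All subcommands accept
`--config file.yaml` with flag values.

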