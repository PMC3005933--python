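"""Node classification and overlapping cluster assembly at one density level.

Given a density level ``k``, every node is assigned exactly one of four
classes and the classes drive cluster assembly:

1. **density** -- local clustering coefficient >= its degree-adaptive
   MinCC threshold; directly connected density nodes seed the same cluster
   (paths through non-density nodes do *not* merge seeds).
2. **border** -- not dense itself but inside the *density region* of some
   density node (its neighbours, minus neighbours with no edge to any other
   neighbour); joins the cluster of every density node whose region holds
   it, so borders may overlap clusters.
3. **affiliated** -- all of its edges lead into a single cluster's member
   set; attachment iterates to a fixed point so chains of pendants resolve
   independently of node order.
4. **interspersed** -- everything else; collected in the inter-module
   layer, outside all clusters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx
from sklearn.base import BaseEstimator

from .density import (
    DensityParameters,
    global_clustering_coefficient,
    min_cc,
)

__all__ = [
    "NodeClass",
    "DensityRegion",
    "Cluster",
    "ClusteringResult",
    "ADHOC",
    "find_density_nodes",
    "density_region",
    "seed_clusters",
    "attach_border_nodes",
    "attach_affiliated_nodes",
    "cluster_graph",
]


class NodeClass(enum.Enum):
    DENSITY = "density"
    BORDER = "border"
    AFFILIATED = "affiliated"
    INTERSPERSED = "interspersed"


@dataclass(frozen=True)
class DensityRegion:
    """A density node's neighbours, excluding neighbours with no edge to
    any other neighbour."""

    owner: str
    members: frozenset


@dataclass
class Cluster:
    id: str
    core: set = field(default_factory=set)
    members: set = field(default_factory=set)
    k: float = float("nan")

    def __post_init__(self) -> None:
        self.members |= self.core


@dataclass
class ClusteringResult:
    """Overlapping clusters plus the inter-module layer at one k.

    Invariants (enforced by :meth:`validate`): every node is in >= 1
    cluster xor in ``inter_module``; density nodes belong to exactly one
    cluster; only border/affiliated nodes may belong to several.
    """

    k: float
    p: float
    clusters: list[Cluster]
    inter_module: set
    classes: dict

    def membership(self) -> dict:
        """node -> sorted list of cluster ids it belongs to."""
        out: dict[str, list[str]] = {}
        for cluster in self.clusters:
            for node in cluster.members:
                out.setdefault(node, []).append(cluster.id)
        return {n: sorted(ids) for n, ids in out.items()}

    def clustered_nodes(self) -> set:
        return set().union(*(c.members for c in self.clusters)) if self.clusters else set()

    def validate(self) -> None:
        clustered = self.clustered_nodes()
        if clustered & self.inter_module:
            raise AssertionError("node in both a cluster and the inter-module layer")
        if set(self.classes) != clustered | self.inter_module:
            raise AssertionError("classes do not cover exactly the assigned nodes")
        counts: dict[str, int] = {}
        for cluster in self.clusters:
            if not cluster.core:
                raise AssertionError(f"cluster {cluster.id} has empty core")
            if not cluster.core <= cluster.members:
                raise AssertionError(f"cluster {cluster.id}: core not within members")
            for node in cluster.members:
                counts[node] = counts.get(node, 0) + 1
        for node, n in counts.items():
            cls = self.classes[node]
            if cls is NodeClass.DENSITY and n != 1:
                raise AssertionError(f"density node {node!r} in {n} clusters")
            if cls is NodeClass.INTERSPERSED:
                raise AssertionError(f"interspersed node {node!r} inside a cluster")
        for node in self.inter_module:
            if self.classes[node] is not NodeClass.INTERSPERSED:
                raise AssertionError(f"{node!r} in inter-module layer but not interspersed")


def find_density_nodes(graph: nx.Graph, params: DensityParameters) -> set:
    """Nodes whose neighbourhood edge count reaches their MinCC threshold.

    The comparison is done on integer edge counts (E >= C*), which is
    exact; it is equivalent to local_clustering_coefficient >= min_cc.
    """
    triangles = nx.triangles(graph)
    dense = set()
    for node, d in graph.degree():
        threshold = min_cc(d, params)
        if threshold.feasible and triangles[node] >= threshold.min_edge_count:
            dense.add(node)
    return dense


def density_region(graph: nx.Graph, density_node) -> DensityRegion:
    """Neighbours of the owner that have >= 1 edge to another neighbour."""
    neighbors = set(graph[density_node])
    members = frozenset(
        v for v in neighbors if any(u in neighbors for u in graph[v] if u != v)
    )
    return DensityRegion(owner=density_node, members=members)


def seed_clusters(graph: nx.Graph, density_nodes: set) -> list[set]:
    """Cluster cores: connected components of the subgraph induced on the
    density nodes (direct density-density edges only)."""
    sub = graph.subgraph(density_nodes)
    return [set(c) for c in nx.connected_components(sub)]


def attach_border_nodes(
    graph: nx.Graph,
    cores: list[set],
    regions: dict,
) -> tuple[list[Cluster], dict]:
    """Attach border nodes: each non-density node inside >= 1 density
    region joins the cluster of every density node whose region holds it.

    Returns the clusters (ids assigned by sorted smallest member, for
    reproducibility) and the class map so far.
    """
    density_nodes = set().union(*cores) if cores else set()
    ordered = sorted(cores, key=lambda core: min(map(str, core)))
    width = max(3, len(str(len(ordered))))
    clusters = [
        Cluster(id=f"C{i:0{width}d}", core=set(core)) for i, core in enumerate(ordered, 1)
    ]
    core_index = {node: c for c in clusters for node in c.core}
    classes = {node: NodeClass.DENSITY for node in density_nodes}
    for owner, region in regions.items():
        cluster = core_index[owner]
        for node in region.members:
            if node in density_nodes:
                continue
            classes[node] = NodeClass.BORDER
            cluster.members.add(node)
    return clusters, classes


def attach_affiliated_nodes(
    graph: nx.Graph, clusters: list[Cluster], classes: dict
) -> dict:
    """Attach affiliated nodes, iterating to a fixed point.

    A yet-unassigned node with degree >= 1 whose entire neighbourhood lies
    inside one cluster's current member set joins that cluster (every such
    cluster, if the neighbourhood sits in an overlap).  Attachment grows
    member sets, which can qualify further nodes, hence the iteration; the
    operator is monotone so the fixed point is order-independent.
    """
    assigned = set().union(*(c.members for c in clusters)) if clusters else set()
    pending = set(graph.nodes) - assigned
    changed = True
    while changed:
        changed = False
        for node in sorted(pending, key=str):
            neighbors = set(graph[node])
            if not neighbors:
                continue
            hosts = [c for c in clusters if neighbors <= c.members]
            if hosts:
                for c in hosts:
                    c.members.add(node)
                classes[node] = NodeClass.AFFILIATED
                pending.discard(node)
                changed = True
    return classes


def cluster_graph(
    graph: nx.Graph,
    params: DensityParameters | None = None,
    *,
    k: float = 3.0,
    p: float | None = None,
    min_size: int | None = None,
) -> ClusteringResult:
    """Run the full pipeline at one density level.

    ``p`` defaults to the graph's global clustering coefficient; a graph
    with no connected triples has no defined coefficient and raises unless
    ``p`` is supplied.  A triangle-free graph (coefficient 0) yields no
    clusters: with no evidence of clustering in the null, no neighbourhood
    can be called dense, and every node is interspersed.
    """
    if params is None:
        if p is None:
            p = global_clustering_coefficient(graph)
        if p == 0.0:
            classes = {node: NodeClass.INTERSPERSED for node in graph.nodes}
            return ClusteringResult(
                k=k, p=0.0, clusters=[], inter_module=set(graph.nodes), classes=classes
            )
        params = DensityParameters(k=k, p=p)

    density_nodes = find_density_nodes(graph, params)
    regions = {v: density_region(graph, v) for v in density_nodes}
    cores = seed_clusters(graph, density_nodes)
    clusters, classes = attach_border_nodes(graph, cores, regions)
    classes = attach_affiliated_nodes(graph, clusters, classes)

    if min_size is not None:
        kept = [c for c in clusters if len(c.members) >= min_size]
        still = set().union(*(c.members for c in kept)) if kept else set()
        for c in clusters:
            if c not in kept:
                for node in c.members - still:
                    classes[node] = NodeClass.INTERSPERSED
        clusters = kept

    clustered = set().union(*(c.members for c in clusters)) if clusters else set()
    inter_module = set(graph.nodes) - clustered
    for node in inter_module:
        classes[node] = NodeClass.INTERSPERSED
    for c in clusters:
        c.k = params.k
    result = ClusteringResult(
        k=params.k, p=params.p, clusters=clusters,
        inter_module=inter_module, classes=classes,
    )
    result.validate()
    return result


class ADHOC(BaseEstimator):
    """Density-based overlapping clusterer for interaction networks.

    Estimator-style wrapper over :func:`cluster_graph`: construct with the
    density level, call :meth:`fit` on a :class:`networkx.Graph` (or an
    iterable of edge pairs), then read the fitted attributes.

    Parameters
    ----------
    k : float, default 3.0
        Density level (clique-size analogue), any real > 1.  3 targets
        neighbourhood density comparable to clique-finding methods run at
        clique size 4.
    edge_prob : float or None, default None
        Background edge probability of the Bernoulli null.  None means use
        the fitted graph's global clustering coefficient.
    min_size : int or None, default None
        Optional minimum cluster size; smaller clusters are dissolved into
        the inter-module layer.  None keeps every cluster (modules as small
        as a core pair plus attachments are biologically meaningful).

    Attributes
    ----------
    result_ : ClusteringResult
    clusters_ : list of Cluster
    inter_module_ : set
    node_classes_ : dict node -> NodeClass
    p_ : float
        Edge probability actually used.
    membership_ : dict node -> list of cluster ids

    Examples
    --------
    >>> import networkx as nx
    >>> from adhocnet.clustering import ADHOC
    >>> g = nx.complete_graph(6)
    >>> model = ADHOC(k=3).fit(g)
    >>> len(model.clusters_)
    1
    """

    def __init__(self, k: float = 3.0, edge_prob: float | None = None,
                 min_size: int | None = None):
        self.k = k
        self.edge_prob = edge_prob
        self.min_size = min_size

    def _as_graph(self, X) -> nx.Graph:
        if isinstance(X, nx.Graph):
            if X.is_directed() or X.is_multigraph():
                raise ValueError("expected a simple undirected graph")
            loops = list(nx.selfloop_edges(X))
            if loops:
                X = X.copy()
                X.remove_edges_from(loops)
            return X
        graph = nx.Graph()
        for a, b in X:
            if a != b:
                graph.add_edge(a, b)
        return graph

    def fit(self, X, y=None):
        """Cluster the network ``X`` (networkx Graph or edge iterable)."""
        graph = self._as_graph(X)
        self.result_ = cluster_graph(
            graph, k=self.k, p=self.edge_prob, min_size=self.min_size
        )
        self.graph_ = graph
        self.clusters_ = self.result_.clusters
        self.inter_module_ = self.result_.inter_module
        self.node_classes_ = self.result_.classes
        self.p_ = self.result_.p
        self.membership_ = self.result_.membership()
        return self
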