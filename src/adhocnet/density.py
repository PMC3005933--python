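"""Degree-adaptive subgraph density model.

A fixed clustering-coefficient cutoff cannot separate dense neighbourhoods
from sparse ones in a scale-free interactome: a degree-2 node trivially
reaches coefficient 1.0 while a degree-50 node essentially never does.  The
model implemented here instead asks, per node, whether its neighbourhood is
*at least as dense as a k-clique* under a Bernoulli null: the minimum
clustering coefficient MinCC for a node of degree ``d`` is the smallest
``C/D`` (``D = d(d-1)/2`` possible neighbour-neighbour edges) such that the
chance probability of observing ``>= C`` edges among the neighbours,
``P(X >= C)`` with ``X ~ Binomial(D, p)``, does not exceed the chance
probability ``p^{k(k-1)/2}`` of an entire k-clique.  ``p`` is the network's
global clustering coefficient, and ``k > 1`` may be any real number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
from scipy import stats

__all__ = [
    "DensityParameters",
    "DensityThreshold",
    "global_clustering_coefficient",
    "local_clustering_coefficient",
    "neighborhood_edge_count",
    "clique_pvalue",
    "binomial_tail",
    "min_cc",
]

# Relative tolerance used when comparing the binomial tail against the
# clique p-value.  The comparison is inclusive (a tie counts as "at least
# as dense as the k-clique"), and exact ties do occur (d=3, k=3 gives
# tail == p^3 on both sides); the guard keeps last-ulp differences between
# tail evaluations from flipping such ties.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class DensityParameters:
    """Density level ``k`` (clique-size analogue, real > 1) and background
    edge probability ``p`` (normally the global clustering coefficient)."""

    k: float
    p: float

    def __post_init__(self) -> None:
        if not self.k > 1:
            raise ValueError(f"density level k must be > 1, got {self.k}")
        if not 0 < self.p <= 1:
            raise ValueError(f"edge probability p must be in (0, 1], got {self.p}")


@dataclass(frozen=True)
class DensityThreshold:
    """Resolved threshold for one degree.

    ``min_edge_count`` is the smallest neighbourhood edge count C* that is
    as significant as a k-clique; ``min_cc = C*/D``.  ``feasible`` is False
    when even a complete neighbourhood (C = D) is less significant than the
    clique, i.e. when D < k(k-1)/2 -- such a degree can never host a
    density node.
    """

    degree: int
    feasible: bool
    min_edge_count: int | None = None
    min_cc: float | None = None


def global_clustering_coefficient(graph: nx.Graph) -> float:
    """3 x (#triangles) / (#connected triples, open and closed).

    Raises ``ValueError`` when the graph has no connected triples (every
    node has degree < 2), in which case the ratio is undefined.
    """
    triples = sum(d * (d - 1) // 2 for _, d in graph.degree())
    if triples == 0:
        raise ValueError(
            "global clustering coefficient undefined: graph has no connected triples"
        )
    closed = sum(nx.triangles(graph).values())  # == 3 * number of triangles
    return closed / triples


def neighborhood_edge_count(graph: nx.Graph, node) -> int:
    """Number of edges among the neighbours of ``node`` (= triangles through it)."""
    if node not in graph:
        raise KeyError(node)
    return nx.triangles(graph, node)


def local_clustering_coefficient(graph: nx.Graph, node) -> float:
    """|edges among neighbours| / (d(d-1)/2); 0.0 for degree < 2."""
    if node not in graph:
        raise KeyError(node)
    d = graph.degree(node)
    if d < 2:
        return 0.0
    return nx.triangles(graph, node) / (d * (d - 1) / 2)


def clique_pvalue(k: float, p: float) -> float:
    """Chance probability ``p^(k(k-1)/2)`` that all edges of a k-clique are
    present; defined for real ``k > 1``."""
    if not k > 1:
        raise ValueError(f"clique size k must be > 1, got {k}")
    if not 0 < p <= 1:
        raise ValueError(f"edge probability p must be in (0, 1], got {p}")
    return p ** (k * (k - 1) / 2.0)


def binomial_tail(D: int, C: int, p: float) -> float:
    """Upper tail ``P(X >= C)`` for ``X ~ Binomial(D, p)``; exactly 1 at C=0."""
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D}")
    if not 0 <= C <= D:
        raise ValueError(f"C must lie in [0, D]={D}, got {C}")
    if C == 0:
        return 1.0
    # binom.sf(C-1) = P(X > C-1) = P(X >= C); computed via the regularised
    # incomplete beta function, accurate deep into the tail.
    return float(stats.binom.sf(C - 1, D, p))


def _tail_significant(D: int, C: int, p: float, threshold: float) -> bool:
    tail = binomial_tail(D, C, p)
    return tail <= threshold or math.isclose(tail, threshold, rel_tol=_TIE_RTOL)


@lru_cache(maxsize=None)
def _min_cc_cached(d: int, k: float, p: float) -> DensityThreshold:
    D = d * (d - 1) // 2
    # Feasibility boundary: the best case C = D has tail p^D, and
    # p^D <= p^{k(k-1)/2}  <=>  D >= k(k-1)/2 (p < 1).  At p == 1 every
    # comparison ties, so C* = 0.
    if p == 1.0:
        return DensityThreshold(degree=d, feasible=True, min_edge_count=0, min_cc=0.0)
    if D < k * (k - 1) / 2.0:
        return DensityThreshold(degree=d, feasible=False)
    threshold = clique_pvalue(k, p)
    # The tail is nonincreasing in C, so the predicate "tail <= threshold"
    # is monotone: binary-search the smallest significant C.
    lo, hi = 0, D  # hi is always significant (checked by feasibility above)
    while lo < hi:
        mid = (lo + hi) // 2
        if _tail_significant(D, mid, p, threshold):
            hi = mid
        else:
            lo = mid + 1
    return DensityThreshold(
        degree=d, feasible=True, min_edge_count=lo, min_cc=lo / D if D else 0.0
    )


def min_cc(d: int, params: DensityParameters) -> DensityThreshold:
    """Degree-adaptive threshold: smallest C* with
    ``P(Binomial(D, p) >= C*) <= p^{k(k-1)/2}`` and ``min_cc = C*/D``.

    Degrees with ``D = d(d-1)/2 < k(k-1)/2`` (in particular d < 2) are
    infeasible: no neighbourhood of that size can match a k-clique.
    Results are memoised per (d, k, p) -- degrees repeat heavily in
    scale-free graphs.
    """
    if d < 0:
        raise ValueError(f"degree must be >= 0, got {d}")
    return _min_cc_cached(int(d), float(params.k), float(params.p))
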