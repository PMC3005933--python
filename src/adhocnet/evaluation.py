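"""Evaluation statistics: GO enrichment, lethality enrichment, discard
rate, betweenness, hub partition and module-based function prediction.

Conventions
-----------
* Enrichment background ``N`` is the analysed graph's node count (the
  "whole network"), not the genome.
* Bonferroni multiplier = number of distinct terms, within the category,
  carried by at least one member of the tested group; p-values are capped
  at 1 after correction and reported as -log10.
* Hubs are nodes of degree strictly greater than the threshold (default
  10); a hub inside >= 1 cluster is a *module hub*, a hub in the
  inter-module layer is an *inter-module hub*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusteringResult
from .density import local_clustering_coefficient
from .graph_io import AnnotationTable

__all__ = [
    "EnrichmentResult",
    "HubPartition",
    "discard_rate",
    "hypergeom_enrichment",
    "enrich_group",
    "mean_cluster_enrichment",
    "lethality_pvalue",
    "lethal_fraction",
    "betweenness",
    "classify_hubs",
    "compare_hub_groups",
    "predict_functions",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one term in one node group.

    N: background size; n: group size; M: term-annotated in background;
    m: term-annotated in group.  ``p_raw`` is the upper tail
    P(X >= m); ``p_corrected`` is Bonferroni-adjusted and capped at 1;
    ``neg_log10_p = -log10(p_corrected)``.
    """

    term: str
    N: int
    n: int
    M: int
    m: int
    p_raw: float
    p_corrected: float
    neg_log10_p: float


def discard_rate(result: ClusteringResult) -> float:
    """Percentage of nodes left in the inter-module layer."""
    total = len(result.clustered_nodes()) + len(result.inter_module)
    if total == 0:
        raise ValueError("discard rate undefined on an empty result")
    return 100.0 * len(result.inter_module) / total


def _hypergeom_upper_tail(N: int, n: int, M: int, m: int) -> float:
    # P(X >= m) with X ~ Hypergeom(N, M, n)
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def hypergeom_enrichment(
    group: set,
    term: str,
    annotations: AnnotationTable,
    background: set,
    n_tests: int | None = None,
) -> EnrichmentResult:
    """Enrichment of ``term`` among ``group`` against ``background``.

    ``n_tests`` overrides the Bonferroni multiplier; by default it is the
    number of distinct terms annotated to at least one group member.
    """
    if not group <= background:
        raise ValueError("group must be a subset of the background")
    N = len(background)
    n = len(group)
    M = sum(1 for v in background if term in annotations.terms_for(v))
    m = sum(1 for v in group if term in annotations.terms_for(v))
    if M > N or n > N:
        raise ValueError("term/group counts exceed the background size")
    p_raw = _hypergeom_upper_tail(N, n, M, m)
    if n_tests is None:
        n_tests = len(set().union(*(annotations.terms_for(v) for v in group))) if group else 1
        n_tests = max(n_tests, 1)
    p_corrected = min(1.0, p_raw * n_tests)
    neg_log10 = -math.log10(p_corrected) if p_corrected > 0 else math.inf
    return EnrichmentResult(
        term=term, N=N, n=n, M=M, m=m,
        p_raw=p_raw, p_corrected=p_corrected, neg_log10_p=neg_log10,
    )


def enrich_group(
    group: set, annotations: AnnotationTable, background: set
) -> list[EnrichmentResult]:
    """Enrichment of every term carried by the group, Bonferroni-corrected
    for the number of terms tested; sorted most significant first (ties by
    term id, for determinism)."""
    terms = sorted(set().union(*(annotations.terms_for(v) for v in group))) if group else []
    results = [
        hypergeom_enrichment(group, term, annotations, background, n_tests=len(terms))
        for term in terms
    ]
    return sorted(results, key=lambda r: (-r.neg_log10_p, r.term))


def best_term(group: set, annotations: AnnotationTable, background: set):
    """Most significant term for a group, or None if no member is annotated."""
    results = enrich_group(group, annotations, background)
    return results[0] if results else None


def mean_cluster_enrichment(
    result: ClusteringResult,
    annotations: AnnotationTable,
    background: set | None = None,
    per_term_average: bool = False,
) -> float:
    """Average -log10 p over clusters.

    Default: each cluster contributes its best (most significant) term;
    clusters without any annotated member contribute 0.  With
    ``per_term_average`` each cluster instead contributes the mean over all
    its tested terms.
    """
    if not result.clusters:
        raise ValueError("mean enrichment undefined with no clusters")
    if background is None:
        background = result.clustered_nodes() | result.inter_module
    values = []
    for cluster in result.clusters:
        results = enrich_group(cluster.members, annotations, background)
        if not results:
            values.append(0.0)
        elif per_term_average:
            values.append(float(np.mean([r.neg_log10_p for r in results])))
        else:
            values.append(results[0].neg_log10_p)
    return float(np.mean(values))


def lethal_fraction(nodes, lethal_status: AnnotationTable) -> float:
    """Fraction of lethal proteins among nodes with *known* status."""
    statuses = [lethal_status.status(v) for v in nodes]
    known = [s for s in statuses if s != "unknown"]
    if not known:
        raise ValueError("no nodes with known lethality status")
    return sum(s == "lethal" for s in known) / len(known)


def lethality_pvalue(
    group: set, lethal_status: AnnotationTable, p_background: float
) -> float:
    """Binomial upper tail P(X >= k_lethal), X ~ Binomial(n_group, p).

    ``n_group`` counts all group members; ``k_lethal`` counts those with
    status lethal.
    """
    if not group:
        raise ValueError("lethality p-value undefined for an empty group")
    if not 0 < p_background < 1:
        raise ValueError(f"p_background must be in (0, 1), got {p_background}")
    n = len(group)
    k = sum(lethal_status.status(v) == "lethal" for v in group)
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p_background))


def betweenness(graph: nx.Graph) -> dict:
    """Unnormalised shortest-path betweenness: for each node i, the sum
    over unordered pairs {s,t} (s,t != i) of the fraction of s-t geodesics
    passing through i; disconnected pairs contribute 0."""
    if len(graph) == 0:
        raise ValueError("betweenness undefined on an empty graph")
    return nx.betweenness_centrality(graph, normalized=False)


@dataclass
class HubPartition:
    """Hubs split by module membership, with per-group topology stats.

    ``group_stats[group]`` carries mean/sd of the intra-group hub-hub
    interaction counts and of the local clustering coefficients, plus the
    raw degree and betweenness samples for distribution comparisons.
    """

    degree_threshold: int
    hubs: set
    module_hubs: set
    inter_module_hubs: set
    group_stats: dict = field(default_factory=dict)


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def classify_hubs(
    graph: nx.Graph,
    result: ClusteringResult,
    threshold: int = 10,
    betweenness_values: dict | None = None,
) -> HubPartition:
    """Partition hubs (degree strictly > threshold) into module hubs
    (inside >= 1 cluster) and inter-module hubs (inter-module layer).

    ``betweenness_values`` may be passed to reuse a precomputed map;
    otherwise betweenness is computed on the spot.
    """
    assigned = result.clustered_nodes() | result.inter_module
    if set(graph.nodes) != assigned:
        raise ValueError("clustering result does not cover the graph's node set")
    hubs = {v for v, d in graph.degree() if d > threshold}
    clustered = result.clustered_nodes()
    module_hubs = hubs & clustered
    inter_module_hubs = hubs & result.inter_module
    if betweenness_values is None:
        betweenness_values = betweenness(graph) if len(graph) else {}
    partition = HubPartition(
        degree_threshold=threshold,
        hubs=hubs,
        module_hubs=module_hubs,
        inter_module_hubs=inter_module_hubs,
    )
    for name, group in (("module_hubs", module_hubs), ("inter_module_hubs", inter_module_hubs)):
        intra = {v: sum(1 for u in graph[v] if u in group) for v in group}
        ccs = {v: local_clustering_coefficient(graph, v) for v in group}
        mean_i, sd_i = _mean_sd(intra.values())
        mean_c, sd_c = _mean_sd(ccs.values())
        partition.group_stats[name] = {
            "n": len(group),
            "intra_group_interactions_mean": mean_i,
            "intra_group_interactions_sd": sd_i,
            "clustering_coefficient_mean": mean_c,
            "clustering_coefficient_sd": sd_c,
            "degrees": sorted(graph.degree(v) for v in group),
            "betweenness": sorted(betweenness_values[v] for v in group),
        }
    return partition


def compare_hub_groups(partition: HubPartition) -> dict:
    """Two-sample (two-sided) Kolmogorov-Smirnov comparison of the degree
    and betweenness distributions of the two hub groups, together with the
    per-group mean +/- sd of intra-group interactions and clustering
    coefficients.  With an empty group the KS tests are flagged and
    skipped."""
    a = partition.group_stats.get("module_hubs", {})
    b = partition.group_stats.get("inter_module_hubs", {})
    report: dict = {
        "degree_threshold": partition.degree_threshold,
        "n_hubs": len(partition.hubs),
        "n_module_hubs": len(partition.module_hubs),
        "n_inter_module_hubs": len(partition.inter_module_hubs),
        "module_hubs": {k: v for k, v in a.items() if not isinstance(v, list)},
        "inter_module_hubs": {k: v for k, v in b.items() if not isinstance(v, list)},
    }
    if not partition.module_hubs or not partition.inter_module_hubs:
        report["ks_tests"] = None
        report["empty_group"] = True
        return report
    report["empty_group"] = False
    ks: dict = {}
    for key in ("degrees", "betweenness"):
        stat, pvalue = stats.ks_2samp(a[key], b[key], alternative="two-sided")
        ks[key] = {"statistic": float(stat), "pvalue": float(pvalue)}
    report["ks_tests"] = ks
    return report


def predict_functions(
    result: ClusteringResult,
    annotations: AnnotationTable,
    neg_log_p_threshold: float = 10.0,
    background: set | None = None,
) -> pd.DataFrame:
    """Module-based function prediction.

    For each cluster whose best term beats the -log10 p threshold
    (strictly), assign that term to every member lacking any annotation in
    the category.  A protein in several qualifying clusters receives every
    such term with its score.  Returns a DataFrame with columns
    (protein, neg_log10_p, predicted_term).
    """
    if background is None:
        background = result.clustered_nodes() | result.inter_module
    rows = []
    for cluster in result.clusters:
        top = best_term(cluster.members, annotations, background)
        if top is None or not top.neg_log10_p > neg_log_p_threshold:
            continue
        for protein in sorted(cluster.members):
            if not annotations.terms_for(protein):
                rows.append(
                    {"protein": protein, "neg_log10_p": top.neg_log10_p,
                     "predicted_term": top.term}
                )
    frame = pd.DataFrame(rows, columns=["protein", "neg_log10_p", "predicted_term"])
    return frame.drop_duplicates().reset_index(drop=True)
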