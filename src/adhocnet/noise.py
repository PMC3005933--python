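"""Noise-robustness protocol: seeded random edge addition + replicate runs.

Interactome data carry many false-positive edges, so a module detector
must tolerate spurious connections.  The protocol adds a fixed fraction of
random interactions to currently unconnected protein pairs, re-clusters,
and aggregates cluster counts (and optionally enrichment) over replicates.
The background probability p is recomputed on every noise-added graph,
since added edges change the null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import cluster_graph
from .evaluation import mean_cluster_enrichment

__all__ = ["NoiseExperimentConfig", "add_noise", "robustness_experiment"]


@dataclass(frozen=True)
class NoiseExperimentConfig:
    """Fractions of |E| to add, replicate count per fraction, density
    level, and the master seed from which every replicate stream derives."""

    fractions: tuple = (0.05, 0.10, 0.15, 0.20, 0.25)
    replicates: int = 100
    k: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if any(not 0 <= f <= 1 for f in fr):
            raise ValueError(f"fractions must lie in [0, 1], got {fr}")
        if list(fr) != sorted(fr):
            raise ValueError("fractions must be sorted ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def add_noise(graph: nx.Graph, fraction: float, rng: np.random.Generator) -> nx.Graph:
    """Return a copy with ``round(fraction * |E|)`` edges added, sampled
    uniformly without replacement from unconnected non-self pairs."""
    if fraction < 0:
        raise ValueError(f"fraction must be >= 0, got {fraction}")
    n_add = int(round(fraction * graph.number_of_edges()))
    noisy = graph.copy()
    if n_add == 0:
        return noisy
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    available = n * (n - 1) // 2 - graph.number_of_edges()
    if n_add > available:
        raise ValueError(
            f"cannot add {n_add} edges: only {available} unconnected pairs exist"
        )
    if available <= 4 * n_add:
        # dense regime: enumerate the non-edges and sample exactly
        non_edges = [
            (a, b) for a, b in itertools.combinations(nodes, 2) if not graph.has_edge(a, b)
        ]
        idx = rng.choice(len(non_edges), size=n_add, replace=False)
        noisy.add_edges_from(non_edges[i] for i in sorted(idx))
        return noisy
    added = 0
    while added < n_add:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = nodes[i], nodes[j]
        if noisy.has_edge(a, b):
            continue
        noisy.add_edge(a, b)
        added += 1
    return noisy


def _replicate_rng(seed: int, fraction_index: int, replicate_index: int) -> np.random.Generator:
    # Per-replicate streams keyed by (fraction, replicate) so partial
    # re-runs reproduce the same table rows.
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(fraction_index, replicate_index))
    return np.random.default_rng(ss)


def robustness_experiment(
    graph: nx.Graph,
    config: NoiseExperimentConfig,
    annotations: dict | None = None,
) -> pd.DataFrame:
    """Run the full noise protocol and aggregate per fraction.

    Returns one row per fraction with mean +/- sd of the cluster count
    (and, when annotation tables are supplied, of the mean best-term
    -log10 p per category).  A fraction of exactly 0 reports the single
    noiseless baseline run with sd 0.
    """
    annotations = annotations or {}
    rows = []
    for fi, fraction in enumerate(config.fractions):
        if fraction == 0:
            replicate_graphs = [graph]
        else:
            replicate_graphs = [
                add_noise(graph, fraction, _replicate_rng(config.seed, fi, ri))
                for ri in range(config.replicates)
            ]
        counts = []
        enrich: dict[str, list[float]] = {c: [] for c in annotations}
        for g in replicate_graphs:
            result = cluster_graph(g, k=config.k)
            counts.append(len(result.clusters))
            for category, table in annotations.items():
                enrich[category].append(
                    mean_cluster_enrichment(result, table) if result.clusters
                    else float("nan")
                )
        arr = np.asarray(counts, dtype=float)
        row = {
            "fraction": fraction,
            "n_replicates": len(replicate_graphs),
            "n_clusters_mean": float(arr.mean()),
            "n_clusters_sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        }
        for category, values in enrich.items():
            varr = np.asarray(values, dtype=float)
            row[f"neglogp_{category}_mean"] = float(np.nanmean(varr)) if varr.size else float("nan")
            row[f"neglogp_{category}_sd"] = (
                float(np.nanstd(varr, ddof=1)) if varr.size > 1 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)
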