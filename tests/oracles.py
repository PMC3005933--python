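"""Independent brute-force oracles.

Everything here is deliberately naive -- exhaustive enumeration, exact
log-space summation, union-find -- and shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from math import comb


def exact_binomial_tail(D: int, C: int, p: float) -> float:
    """P(X >= C), X ~ Binomial(D, p), by log-space term summation."""
    if C == 0:
        return 1.0
    if p == 0:
        return 0.0
    if p == 1:
        return 1.0
    logs = []
    lp, lq = math.log(p), math.log(1 - p)
    for i in range(C, D + 1):
        logs.append(math.lgamma(D + 1) - math.lgamma(i + 1) - math.lgamma(D - i + 1)
                    + i * lp + (D - i) * lq)
    m = max(logs)
    return math.exp(m) * sum(math.exp(x - m) for x in logs)


def exact_hypergeom_tail(N: int, n: int, M: int, m: int) -> float:
    """P(X >= m) for drawing n from N with M marked, by exact summation."""
    total = comb(N, n)
    acc = 0
    for i in range(m, min(n, M) + 1):
        acc += comb(M, i) * comb(N - M, n - i)
    return acc / total


def min_cc_scan(d: int, k: float, p: float):
    """Linear scan for the smallest C with tail <= p^{k(k-1)/2} (inclusive,
    with the same 1e-9 tie tolerance the definition prescribes).  Returns
    (feasible, C*)."""
    D = d * (d - 1) // 2
    threshold = p ** (k * (k - 1) / 2.0)
    for C in range(D + 1):
        tail = exact_binomial_tail(D, C, p)
        if tail <= threshold or math.isclose(tail, threshold, rel_tol=1e-9):
            return True, C
    return False, None


def gcc_by_triple_enumeration(graph) -> float:
    """3 x triangles / connected triples, by enumerating all length-2 paths."""
    closed = open_or_closed = 0
    for center in graph:
        for a, b in itertools.combinations(graph[center], 2):
            open_or_closed += 1
            if graph.has_edge(a, b):
                closed += 1
    return closed / open_or_closed


def lcc_by_pair_count(graph, node) -> float:
    neighbors = list(graph[node])
    d = len(neighbors)
    if d < 2:
        return 0.0
    e = sum(1 for a, b in itertools.combinations(neighbors, 2) if graph.has_edge(a, b))
    return e / (d * (d - 1) / 2)


def betweenness_by_path_enumeration(graph) -> dict:
    """Unnormalised betweenness via BFS geodesic counting per pair."""
    nodes = list(graph)
    scores = {v: 0.0 for v in nodes}

    def geodesics(s, t):
        # all shortest s-t paths by BFS layering + DFS backtracking
        dist = {s: 0}
        parents = {s: []}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in graph[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    parents[w] = [u]
                    queue.append(w)
                elif dist[w] == dist[u] + 1:
                    parents[w].append(u)
        if t not in dist:
            return []
        paths = []

        def back(v, acc):
            if v == s:
                paths.append(acc + [s])
                return
            for u in parents[v]:
                back(u, acc + [v])

        back(t, [])
        return paths

    for s, t in itertools.combinations(nodes, 2):
        paths = geodesics(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for path in paths if v in path)
            scores[v] += through / len(paths)
    return scores


def components_by_union_find(nodes, edges):
    """Connected components over the given node set using only the edges
    whose both endpoints are in it."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        if a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=lambda s: sorted(map(str, s)))
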