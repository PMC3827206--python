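"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive and written against plain Python
structures (adjacency sets) so it shares no code path with the package:
distances come from hand-rolled BFS, orbits from full permutation
enumeration, entropies from direct formula evaluation with math.log2.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, deque

import numpy as np

from structmark.graph_core import Graph


def adjacency_sets(g: Graph) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {v: set() for v in g.vertex_ids}
    for u, v in g.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def all_pairs_distances(g: Graph) -> dict[str, dict[str, int]]:
    adj = adjacency_sets(g)
    return {v: bfs_distances(adj, v) for v in g.vertex_ids}


def largest_component_vertices(g: Graph) -> list[str]:
    adj = adjacency_sets(g)
    seen: set[str] = set()
    comps = []
    for v in g.vertex_ids:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps[0]


def scope(g: Graph) -> Graph:
    """Largest-component working graph, mirroring the package rule."""
    if len(largest_component_vertices(g)) == g.n:
        return g
    return g.induced_subgraph(largest_component_vertices(g))


def entropy_bits(weights) -> float:
    total = float(sum(weights))
    h = 0.0
    for w in weights:
        if w > 0:
            p = w / total
            h -= p * math.log2(p)
    return max(0.0, h)


# ---------------------------------------------------------------------------
# Orbits by full permutation enumeration (n <= 8)


def brute_force_automorphisms(g: Graph) -> list[tuple[str, ...]]:
    vs = list(g.vertex_ids)
    edges = {frozenset(e) for e in g.edges}
    autos = []
    for perm in itertools.permutations(vs):
        m = dict(zip(vs, perm))
        if {frozenset((m[u], m[v])) for u, v in g.edges} == edges:
            autos.append(perm)
    return autos


def brute_force_orbits(g: Graph) -> tuple[list[tuple[str, ...]], int]:
    vs = list(g.vertex_ids)
    autos = brute_force_automorphisms(g)
    parent = {v: v for v in vs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in autos:
        for a, b in zip(vs, perm):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    blocks: dict[str, list[str]] = {}
    for v in vs:
        blocks.setdefault(find(v), []).append(v)
    out = sorted(tuple(sorted(b)) for b in blocks.values())
    return out, len(autos)


def brute_force_isomorphic(g1: Graph, g2: Graph) -> bool:
    if g1.n != g2.n or g1.m != g2.m:
        return False
    vs1, vs2 = list(g1.vertex_ids), list(g2.vertex_ids)
    e2 = {frozenset(e) for e in g2.edges}
    for perm in itertools.permutations(vs2):
        m = dict(zip(vs1, perm))
        if {frozenset((m[u], m[v])) for u, v in g1.edges} == e2:
            return True
    return False


# ---------------------------------------------------------------------------
# Entropy descriptor oracles (connected scope assumed where distances used)


def oracle_dehmer_fV(g: Graph) -> float:
    g = scope(g)
    d = all_pairs_distances(g)
    f = [(g.n - 1) / sum(d[v].values()) for v in g.vertex_ids]
    return entropy_bits(f)


def oracle_dehmer_fP(g: Graph) -> float:
    g = scope(g)
    d = all_pairs_distances(g)
    rho = max(max(row.values()) for row in d.values())
    f = []
    for v in g.vertex_ids:
        total = 0.0
        for j in range(1, rho + 1):
            cj = rho - j + 1
            total += cj * sum(1 for w in g.vertex_ids if d[v][w] == j)
        f.append(total)
    return entropy_bits(f)


def oracle_topological_info_content(g: Graph) -> float:
    blocks, _ = brute_force_orbits(g)
    return entropy_bits([len(b) for b in blocks])


def oracle_symmetry_index(g: Graph) -> float:
    blocks, order = brute_force_orbits(g)
    n = g.n
    term = sum(
        (len(b) / n) * math.log2(len(b)) for b in blocks if len(b) > 1
    )
    return math.log2(order) + term


def oracle_vertex_complexity(g: Graph) -> float:
    g = scope(g)
    d = all_pairs_distances(g)
    hs = []
    for v in g.vertex_ids:
        counts = Counter(d[v].values())  # includes distance 0 (self)
        hs.append(entropy_bits(list(counts.values())))
    return sum(hs) / g.n


def oracle_info_distance_degree(g: Graph) -> float:
    g = scope(g)
    d = all_pairs_distances(g)
    sums = Counter(sum(d[v].values()) for v in g.vertex_ids)
    return entropy_bits(list(sums.values()))


def oracle_info_edge_equality(g: Graph) -> float:
    deg = g.degree()
    blocks = Counter(tuple(sorted((deg[u], deg[v]))) for u, v in g.edges)
    return entropy_bits(list(blocks.values()))


def oracle_bonchev_ID(g: Graph) -> float:
    g = scope(g)
    d = all_pairs_distances(g)
    vals = [
        d[u][v]
        for i, u in enumerate(g.vertex_ids)
        for v in g.vertex_ids[i + 1:]
    ]
    return entropy_bits(list(Counter(vals).values()))


def oracle_bonchev_IDW(g: Graph) -> float:
    g = scope(g)
    d = all_pairs_distances(g)
    vals = [
        d[u][v]
        for i, u in enumerate(g.vertex_ids)
        for v in g.vertex_ids[i + 1:]
    ]
    w = sum(vals)
    out = w * math.log2(w) if w > 0 else 0.0
    for dist, k in Counter(vals).items():
        if dist > 0:
            out -= k * dist * math.log2(dist)
    return out


def oracle_balaban_J(g: Graph) -> float:
    g = scope(g)
    d = all_pairs_distances(g)
    s = {v: sum(d[v].values()) for v in g.vertex_ids}
    mu = g.m - g.n + 1
    return g.m / (mu + 1) * sum(
        1.0 / math.sqrt(s[u] * s[v]) for u, v in g.edges
    )


ENTROPY_ORACLES = {
    "dehmer_fV": oracle_dehmer_fV,
    "topological_info_content": oracle_topological_info_content,
    "vertex_complexity": oracle_vertex_complexity,
    "info_distance_degree": oracle_info_distance_degree,
    "info_edge_equality": oracle_info_edge_equality,
    "balaban_J": oracle_balaban_J,
    "symmetry_index": oracle_symmetry_index,
    "bonchev_ID": oracle_bonchev_ID,
    "dehmer_fP": oracle_dehmer_fP,
    "bonchev_IDW": oracle_bonchev_IDW,
}


# ---------------------------------------------------------------------------
# ndv oracle: O(N^2) pairwise relation + transitive closure


def oracle_ndv(values, tol: float = 0.0) -> int:
    v = np.asarray(values, dtype=float)
    n = v.size
    related = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            related[i, j] = abs(v[i] - v[j]) <= tol * max(abs(v[i]), abs(v[j]))
    # transitive closure by boolean matrix powering
    closure = related.copy()
    while True:
        nxt = closure | (closure @ closure)
        if (nxt == closure).all():
            break
        closure = nxt
    colliding = 0
    for i in range(n):
        if (closure[i] & (np.arange(n) != i)).any():
            colliding += 1
    return colliding


# ---------------------------------------------------------------------------
# Confusion-matrix metric oracle


def oracle_macro_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Macro metrics from counts with class A positive (tp/fn) and class B
    negative (tn/fp)."""
    sens_a = tp / (tp + fn) if tp + fn else 0.0
    sens_b = tn / (tn + fp) if tn + fp else 0.0
    prec_a = tp / (tp + fp) if tp + fp else 0.0
    prec_b = tn / (tn + fn) if tn + fn else 0.0
    f_a = (2 * prec_a * sens_a / (prec_a + sens_a)
           if prec_a + sens_a else 0.0)
    f_b = (2 * prec_b * sens_b / (prec_b + sens_b)
           if prec_b + sens_b else 0.0)
    return {
        "sensitivity": (sens_a + sens_b) / 2,
        "specificity": (sens_b + sens_a) / 2,
        "precision": (prec_a + prec_b) / 2,
        "recall": (sens_a + sens_b) / 2,
        "accuracy": (tp + tn) / (tp + fn + tn + fp),
        "f_score": (f_a + f_b) / 2,
    }
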