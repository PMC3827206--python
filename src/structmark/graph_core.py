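"""Undirected simple labelled graphs and their derived matrices.

This module is the foundation of the descriptor pipeline: it defines the
:class:`Graph` value type (canonical sorted vertex order, validated edge
set), the adjacency/distance/Laplacian matrix bundle
(:class:`GraphMatrices`), exact isomorphism testing, and exact
automorphism-orbit computation (:func:`automorphism_orbits`), which the
symmetry-based entropy descriptors require.

Disconnected graphs are handled by a single rule used throughout the
package: distance-based quantities are computed on the largest connected
component, ties broken by the lexicographically smallest vertex label.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "Graph",
    "GraphMatrices",
    "OrbitPartition",
    "DistanceScope",
    "build_matrices",
    "are_isomorphic",
    "automorphism_orbits",
    "drop_isomorphic_duplicates",
    "assert_non_isomorphic",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
]


class DistanceScope(str, Enum):
    """How to compute shortest-path distances on disconnected graphs."""

    largest_component = "largest_component"
    require_connected = "require_connected"


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with string vertex labels.

    Vertices are stored in sorted order so matrix views, spectra and file
    outputs are byte-reproducible. Edges are unordered label pairs stored
    as ``(min, max)`` tuples. No self-loops, no duplicates.
    """

    vertex_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        vs = tuple(sorted(self.vertex_ids))
        if len(set(vs)) != len(vs):
            raise ValueError("duplicate vertex labels")
        object.__setattr__(self, "vertex_ids", vs)
        vset = set(vs)
        canon = set()
        for e in self.edges:
            u, v = e
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in vset or v not in vset:
                raise ValueError(f"edge {e!r} has endpoint outside vertex set")
            canon.add((u, v) if u < v else (v, u))
        object.__setattr__(self, "edges", frozenset(canon))

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        vertices: Iterable[str] | None = None,
    ) -> "Graph":
        """Build a graph from an edge iterable, optionally adding isolated
        vertices listed in *vertices*."""
        edges = [(str(u), str(v)) for u, v in edges]
        vs = {u for e in edges for u in e}
        if vertices is not None:
            vs.update(str(v) for v in vertices)
        return cls(tuple(sorted(vs)), frozenset(edges))

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        return cls.from_edges(
            ((str(u), str(v)) for u, v in g.edges()),
            vertices=(str(v) for v in g.nodes()),
        )

    # -- basic views -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertex_ids)

    @property
    def m(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        d = {v: 0 for v in self.vertex_ids}
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix in canonical vertex order."""
        idx = {v: i for i, v in enumerate(self.vertex_ids)}
        a = np.zeros((self.n, self.n))
        for u, v in self.edges:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertex_ids)
        g.add_edges_from(self.edges)
        return g

    def induced_subgraph(self, vertices: Iterable[str]) -> "Graph":
        keep = set(vertices) & set(self.vertex_ids)
        edges = frozenset(e for e in self.edges if e[0] in keep and e[1] in keep)
        return Graph(tuple(sorted(keep)), edges)

    def relabel(self, mapping: Mapping[str, str]) -> "Graph":
        return Graph.from_edges(
            ((mapping[u], mapping[v]) for u, v in self.edges),
            vertices=(mapping[v] for v in self.vertex_ids),
        )

    def connected_components(self) -> list[tuple[str, ...]]:
        """Components as vertex tuples, each sorted, ordered by
        (-size, smallest label)."""
        if self.n == 0:
            return []
        a = csr_matrix(self.adjacency())
        k, labels = connected_components(a, directed=False)
        comps: list[list[str]] = [[] for _ in range(k)]
        for v, c in zip(self.vertex_ids, labels):
            comps[c].append(v)
        out = [tuple(sorted(c)) for c in comps]
        out.sort(key=lambda c: (-len(c), c[0]))
        return out

    def is_connected(self) -> bool:
        return self.n > 0 and len(self.connected_components()) == 1

    def largest_component(self) -> "Graph":
        """Largest connected component; ties by smallest vertex label."""
        comps = self.connected_components()
        if not comps:
            raise ValueError("empty graph has no components")
        return self.induced_subgraph(comps[0])


@dataclass(frozen=True)
class GraphMatrices:
    """Adjacency, shortest-path distance and Laplacian matrices of a graph.

    ``adjacency`` and ``laplacian`` cover the full graph in canonical
    vertex order. ``distance`` covers ``distance_vertex_ids`` — the full
    vertex set when the graph is connected, otherwise the largest
    component (see :class:`DistanceScope`).
    """

    vertex_ids: tuple[str, ...]
    adjacency: np.ndarray
    laplacian: np.ndarray
    distance: np.ndarray
    distance_vertex_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.vertex_ids)

    @property
    def m(self) -> int:
        return int(round(self.adjacency.sum() / 2.0))


@dataclass(frozen=True)
class OrbitPartition:
    """Vertex orbits of the automorphism group, plus the group order."""

    blocks: tuple[tuple[str, ...], ...]
    group_order: int

    def __post_init__(self) -> None:
        blocks = tuple(sorted(tuple(sorted(b)) for b in self.blocks))
        object.__setattr__(self, "blocks", blocks)
        seen: set[str] = set()
        for b in blocks:
            if seen & set(b):
                raise ValueError("orbit blocks overlap")
            seen.update(b)
        if self.group_order < 1:
            raise ValueError("group order must be positive")
        if self.group_order == 1 and any(len(b) > 1 for b in blocks):
            raise ValueError("trivial group forces singleton orbits")

    def block_sizes(self) -> list[int]:
        return [len(b) for b in self.blocks]


def build_matrices(
    g: Graph,
    distance_scope: DistanceScope | str = DistanceScope.largest_component,
) -> GraphMatrices:
    """Derive A, D and L for *g* in canonical vertex order.

    Parameters
    ----------
    g
        Graph with at least 2 vertices.
    distance_scope
        ``largest_component`` computes D on the largest connected
        component of a disconnected graph; ``require_connected`` raises
        instead.
    """
    scope = DistanceScope(distance_scope)
    if g.n < 2:
        raise ValueError("graph must have at least 2 vertices")
    a = g.adjacency()
    lap = np.diag(a.sum(axis=1)) - a
    comps = g.connected_components()
    if len(comps) == 1:
        dist_vs = g.vertex_ids
        dist = shortest_path(csr_matrix(a), directed=False, unweighted=True)
    else:
        if scope is DistanceScope.require_connected:
            raise ValueError("graph is disconnected")
        sub = g.induced_subgraph(comps[0])
        dist_vs = sub.vertex_ids
        dist = shortest_path(
            csr_matrix(sub.adjacency()), directed=False, unweighted=True
        )
    return GraphMatrices(
        vertex_ids=g.vertex_ids,
        adjacency=a,
        laplacian=lap,
        distance=np.asarray(dist, dtype=float),
        distance_vertex_ids=tuple(dist_vs),
    )


# ---------------------------------------------------------------------------
# Isomorphism


def are_isomorphic(g1: Graph, g2: Graph) -> bool:
    """Exact isomorphism test (VF2++ backtracking, not heuristic)."""
    if g1.n != g2.n or g1.m != g2.m:
        return False
    if sorted(g1.degree().values()) != sorted(g2.degree().values()):
        return False
    return nx.vf2pp_is_isomorphic(g1.to_networkx(), g2.to_networkx())


def _iso_invariant(g: Graph) -> tuple:
    # cheap prescreen key: order, size, degree sequence, sorted spectrum
    eigs = np.linalg.eigvalsh(g.adjacency()) if g.n else np.array([])
    return (g.n, g.m, tuple(sorted(g.degree().values())),
            tuple(np.round(eigs, 8)))


def drop_isomorphic_duplicates(
    graphs: Sequence[Graph],
) -> tuple[list[int], list[int]]:
    """Indices of representatives (first of each isomorphism class) and of
    dropped duplicates."""
    buckets: dict[tuple, list[int]] = {}
    keep: list[int] = []
    dropped: list[int] = []
    for i, g in enumerate(graphs):
        key = _iso_invariant(g)
        dup = False
        for j in buckets.get(key, []):
            if are_isomorphic(graphs[j], g):
                dup = True
                break
        if dup:
            dropped.append(i)
        else:
            buckets.setdefault(key, []).append(i)
            keep.append(i)
    return keep, dropped


def assert_non_isomorphic(graphs: Sequence[Graph], group: str = "") -> None:
    """Raise ``ValueError`` if any two graphs are isomorphic."""
    _, dropped = drop_isomorphic_duplicates(graphs)
    if dropped:
        where = f" in group {group!r}" if group else ""
        raise ValueError(
            f"{len(dropped)} isomorphic duplicate graph(s){where}: "
            f"indices {dropped}"
        )


# ---------------------------------------------------------------------------
# Automorphism orbits (exact, WL refinement used only for pruning)


def _wl_refine(adj: list[set[int]], colors: list[int]) -> list[int]:
    """Iterate 1-WL colour refinement to a stable partition."""
    n = len(adj)
    while True:
        sigs = [
            (colors[v], tuple(sorted(colors[u] for u in adj[v])))
            for v in range(n)
        ]
        palette = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new = [palette[s] for s in sigs]
        if len(set(new)) == len(set(colors)):
            return new
        colors = new


def _individualize(colors: list[int], v: int) -> list[int]:
    new = [2 * c for c in colors]
    new[v] -= 1  # unique colour strictly below its old class
    return new


def _extend_mapping(
    adj: list[set[int]], colors: list[int], pinned: dict[int, int]
) -> bool:
    """Does a colour- and adjacency-preserving bijection extending *pinned*
    exist? Plain backtracking; candidate sets limited to WL colour classes."""
    n = len(adj)
    for s, t in pinned.items():
        if colors[s] != colors[t]:
            return False
    classes: dict[int, list[int]] = {}
    for v in range(n):
        classes.setdefault(colors[v], []).append(v)
    order = sorted(
        (v for v in range(n) if v not in pinned),
        key=lambda v: (len(classes[colors[v]]), colors[v], v),
    )
    mapping = dict(pinned)
    used = set(mapping.values())
    # pinned pairs must already be mutually consistent
    pv = list(pinned)
    for i, a in enumerate(pv):
        for b in pv[i + 1:]:
            if (b in adj[a]) != (mapping[b] in adj[mapping[a]]):
                return False
    if len(used) != len(mapping):
        return False

    def backtrack(k: int) -> bool:
        if k == len(order):
            return True
        v = order[k]
        for u in classes[colors[v]]:
            if u in used:
                continue
            ok = all(
                (w in adj[v]) == (mw in adj[u]) for w, mw in mapping.items()
            )
            if not ok:
                continue
            mapping[v] = u
            used.add(u)
            if backtrack(k + 1):
                return True
            del mapping[v]
            used.discard(u)
        return False

    return backtrack(0)


def _group_order(adj: list[set[int]], colors: list[int]) -> int:
    """|Aut| by orbit–stabilizer recursion on individualized colourings."""
    colors = _wl_refine(adj, colors)
    n = len(adj)
    classes: dict[int, list[int]] = {}
    for v in range(n):
        classes.setdefault(colors[v], []).append(v)
    target = None
    for v in range(n):
        if len(classes[colors[v]]) > 1:
            target = v
            break
    if target is None:
        return 1
    orbit = 0
    for u in classes[colors[target]]:
        if u == target or _extend_mapping(adj, colors, {target: u}):
            orbit += 1
    return orbit * _group_order(adj, _individualize(colors, target))


def automorphism_orbits(g: Graph, cap: int = 500) -> OrbitPartition:
    """Exact vertex orbits of Aut(g) and the group order.

    WL colour refinement prunes the backtracking search but never decides
    orbit membership on its own — every merge is witnessed by an explicit
    automorphism.

    Parameters
    ----------
    g : Graph
    cap : int
        Maximum vertex count accepted (guards the exact search).
    """
    if g.n > cap:
        raise ValueError(f"graph order {g.n} exceeds cap {cap}")
    if g.n == 0:
        return OrbitPartition(blocks=(), group_order=1)
    idx = {v: i for i, v in enumerate(g.vertex_ids)}
    adj: list[set[int]] = [set() for _ in range(g.n)]
    for u, v in g.edges:
        adj[idx[u]].add(idx[v])
        adj[idx[v]].add(idx[u])
    degrees = [len(a) for a in adj]
    palette = {d: i for i, d in enumerate(sorted(set(degrees)))}
    colors = _wl_refine(adj, [palette[d] for d in degrees])

    classes: dict[int, list[int]] = {}
    for v in range(g.n):
        classes.setdefault(colors[v], []).append(v)
    blocks: list[tuple[str, ...]] = []
    for members in classes.values():
        remaining = list(members)
        while remaining:
            rep = remaining.pop(0)
            orbit = [rep]
            rest = []
            for u in remaining:
                if _extend_mapping(adj, colors, {rep: u}):
                    orbit.append(u)
                else:
                    rest.append(u)
            remaining = rest
            blocks.append(tuple(sorted(g.vertex_ids[v] for v in orbit)))
    order = _group_order(adj, colors)
    return OrbitPartition(blocks=tuple(blocks), group_order=order)


# ---------------------------------------------------------------------------
# I/O


def write_edge_list(
    g: Graph, path: str | Path, vertices_path: str | Path | None = None
) -> None:
    """Two whitespace-separated labels per line; isolated vertices go to an
    optional sidecar file, one label per line."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")
    if vertices_path is not None:
        with Path(vertices_path).open("w") as fh:
            for v in g.vertex_ids:
                fh.write(v + "\n")


def read_edge_list(
    path: str | Path, vertices_path: str | Path | None = None
) -> Graph:
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed edge line: {line!r}")
        edges.append((parts[0], parts[1]))
    vertices: list[str] | None = None
    if vertices_path is not None:
        vertices = [
            ln.strip()
            for ln in Path(vertices_path).read_text().splitlines()
            if ln.strip()
        ]
    return Graph.from_edges(edges, vertices=vertices)


def write_graphml(g: Graph, path: str | Path) -> None:
    nx.write_graphml(g.to_networkx(), str(path))


def read_graphml(path: str | Path) -> Graph:
    return Graph.from_networkx(nx.read_graphml(str(path)))
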