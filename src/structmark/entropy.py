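"""Entropy and information-theoretic structural descriptors.

Ten measures form the default battery, in stable column order:

1.  ``dehmer_fV``       — information-functional entropy, closeness weights
2.  ``topological_info_content`` — entropy of automorphism-orbit sizes
3.  ``vertex_complexity``        — mean entropy of per-vertex distance profiles
4.  ``info_distance_degree``     — entropy of the distance-degree partition
5.  ``info_edge_equality``       — entropy of the endpoint-degree edge partition
6.  ``balaban_J``                — distance-degree connectivity index
7.  ``symmetry_index``           — group-order + orbit-size log-mean term
8.  ``bonchev_ID``               — entropy of the distance-value distribution
9.  ``dehmer_fP``       — information-functional entropy, j-sphere weights
10. ``bonchev_IDW``              — magnitude (Wiener-weighted) variant

All entropies are in bits. The exact weighting functionals and partition
criteria are reconstructions (see keyword arguments); each is swappable.
Distance-based measures follow the package-wide largest-component rule.
"""

from __future__ import annotations

import math
from collections import Counter
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np

from .graph_core import (
    DistanceScope,
    Graph,
    GraphMatrices,
    OrbitPartition,
    automorphism_orbits,
    build_matrices,
)

__all__ = [
    "FunctionalKind",
    "ENTROPY_DESCRIPTOR_NAMES",
    "shannon_entropy",
    "partition_entropy",
    "dehmer_entropy",
    "topological_info_content",
    "partition_entropies",
    "PartitionEntropies",
    "balaban_J",
    "symmetry_index",
    "entropy_descriptors",
]


class FunctionalKind(str, Enum):
    """Vertex weighting used by the information-functional entropies."""

    fV_centrality = "fV_centrality"
    fP_spheres = "fP_spheres"


#: Stable column order, matching the order the measures are listed above.
ENTROPY_DESCRIPTOR_NAMES: tuple[str, ...] = (
    "dehmer_fV",
    "topological_info_content",
    "vertex_complexity",
    "info_distance_degree",
    "info_edge_equality",
    "balaban_J",
    "symmetry_index",
    "bonchev_ID",
    "dehmer_fP",
    "bonchev_IDW",
)


def shannon_entropy(p: Sequence[float]) -> float:
    """Shannon entropy −Σ p log2 p in bits, with 0·log 0 := 0.

    *p* must be non-negative and sum to 1 within 1e-9.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return 0.0
    if (arr < 0).any():
        raise ValueError("negative probability entry")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {arr.sum()}, not 1")
    nz = arr[arr > 0]
    return max(0.0, float(-(nz * np.log2(nz)).sum()))


def partition_entropy(block_sizes: Sequence[int]) -> float:
    """Entropy of a partition given its block sizes."""
    sizes = np.asarray(block_sizes, dtype=float)
    total = sizes.sum()
    if total == 0:
        return 0.0
    return shannon_entropy(sizes / total)


def _distance_scope(g: Graph) -> tuple[Graph, np.ndarray]:
    """Connected working graph and its distance matrix (largest component
    for disconnected inputs). Scope must hold at least two vertices."""
    comp = g if g.is_connected() else g.largest_component()
    if comp.n < 2:
        raise ValueError(
            "distance-based descriptor needs a component with >= 2 vertices"
        )
    mats = build_matrices(comp, DistanceScope.require_connected)
    return comp, mats.distance


def _sphere_counts(dist: np.ndarray) -> np.ndarray:
    """counts[v, j] = number of vertices at distance exactly j from v,
    j = 0..diameter (j=0 counts v itself)."""
    rho = int(dist.max())
    n = dist.shape[0]
    counts = np.zeros((n, rho + 1), dtype=int)
    for j in range(rho + 1):
        counts[:, j] = (dist == j).sum(axis=1)
    return counts


def dehmer_entropy(
    g: Graph,
    functional_kind: FunctionalKind | str = FunctionalKind.fV_centrality,
    coefficients: Sequence[float] | None = None,
) -> float:
    """Information-functional graph entropy in bits.

    A positive weight f(v) is assigned to every vertex, normalized into a
    probability distribution p(v) = f(v)/Σf, and the Shannon entropy of p
    is returned.

    ``fV_centrality`` uses closeness centrality (n−1)/Σ_u d(v,u).
    ``fP_spheres`` uses f(v) = Σ_{j=1..ρ} c_j |S_j(v)| where S_j(v) is the
    j-sphere around v, ρ the diameter, and c_j = ρ − j + 1 unless
    *coefficients* overrides the preset. Coefficients must be positive.
    """
    kind = FunctionalKind(functional_kind)
    _, dist = _distance_scope(g)
    n = dist.shape[0]
    if kind is FunctionalKind.fV_centrality:
        f = (n - 1) / dist.sum(axis=1)
    else:
        rho = int(dist.max())
        if coefficients is None:
            c = np.arange(rho, 0, -1, dtype=float)  # rho - j + 1
        else:
            c = np.asarray(coefficients, dtype=float)
            if c.size < rho:
                raise ValueError(
                    f"need at least {rho} coefficients, got {c.size}"
                )
            c = c[:rho]
        if (c <= 0).any():
            raise ValueError("sphere coefficients must be positive")
        spheres = _sphere_counts(dist)[:, 1:]  # drop j=0
        f = spheres @ c
    if (f <= 0).any():
        raise ValueError("information functional produced non-positive value")
    return shannon_entropy(f / f.sum())


def topological_info_content(
    g: Graph, orbits: OrbitPartition | None = None
) -> float:
    """Entropy of the automorphism-orbit size distribution (bits).

    Zero exactly when the graph is vertex-transitive; log2 n when the
    graph is asymmetric.
    """
    if orbits is None:
        orbits = automorphism_orbits(g)
    return partition_entropy(orbits.block_sizes())


class PartitionEntropies(NamedTuple):
    info_distance_degree: float
    info_edge_equality: float
    bonchev_ID: float
    bonchev_IDW: float
    vertex_complexity: float


def partition_entropies(
    g: Graph, mats: GraphMatrices | None = None
) -> PartitionEntropies:
    """The five partition/distribution entropies over distances and degrees.

    - ``info_distance_degree``: vertices partitioned by distance degree
      (row sum of D).
    - ``info_edge_equality``: edges partitioned by unordered endpoint-degree
      pair (full graph, no distance needed).
    - ``bonchev_ID``: entropy of the distance-value distribution over the
      n(n−1)/2 vertex pairs.
    - ``bonchev_IDW``: W·log2 W − Σ_d k_d·d·log2 d with W the Wiener sum and
      k_d the number of pairs at distance d.
    - ``vertex_complexity``: mean over vertices of the entropy of the
      vertex's distance profile (counts at each distance j ≥ 0, self
      included at j = 0, divided by n).
    """
    comp, dist = _distance_scope(g)
    n = dist.shape[0]

    s = dist.sum(axis=1)
    dd_blocks = Counter(np.round(s, 9).tolist())
    info_distance_degree = partition_entropy(list(dd_blocks.values()))

    deg = g.degree()
    edge_blocks = Counter(
        tuple(sorted((deg[u], deg[v]))) for u, v in g.edges
    )
    info_edge_equality = partition_entropy(list(edge_blocks.values()))

    iu = np.triu_indices(n, k=1)
    pair_d = dist[iu].astype(int)
    k_d = Counter(pair_d.tolist())
    bonchev_id = partition_entropy(list(k_d.values()))

    wiener = float(pair_d.sum())
    idw = wiener * np.log2(wiener) if wiener > 0 else 0.0
    for d, k in k_d.items():
        if d > 0:
            idw -= k * d * np.log2(d)
    bonchev_idw = float(idw)

    profiles = _sphere_counts(dist)  # includes j = 0
    vc = float(
        np.mean([partition_entropy(row[row > 0]) for row in profiles])
    )

    return PartitionEntropies(
        info_distance_degree=info_distance_degree,
        info_edge_equality=info_edge_equality,
        bonchev_ID=bonchev_id,
        bonchev_IDW=bonchev_idw,
        vertex_complexity=vc,
    )


def balaban_J(g: Graph, mats: GraphMatrices | None = None) -> float:
    """Balaban's distance-degree connectivity index.

    J = m/(μ+1) · Σ_{(u,v)∈E} (s_u s_v)^{−1/2} with s_v the distance
    degree of v and μ = m − n + 1 the cyclomatic number; computed on the
    largest component for disconnected inputs.
    """
    comp, dist = _distance_scope(g)
    s = dist.sum(axis=1)
    idx = {v: i for i, v in enumerate(comp.vertex_ids)}
    n, m = comp.n, comp.m
    mu = m - n + 1
    total = sum(
        1.0 / np.sqrt(s[idx[u]] * s[idx[v]]) for u, v in comp.edges
    )
    return float(m / (mu + 1) * total)


def symmetry_index(g: Graph, orbits: OrbitPartition | None = None) -> float:
    """Entropic symmetry index (bits):
    log2|Aut(g)| + Σ_blocks (|b|/n)·log2|b|.

    Zero exactly for asymmetric graphs.
    """
    if orbits is None:
        orbits = automorphism_orbits(g)
    n = sum(orbits.block_sizes())
    term = sum(
        (b / n) * np.log2(b) for b in orbits.block_sizes() if b > 1
    )
    return float(math.log2(orbits.group_order) + term)


def entropy_descriptors(
    g: Graph,
    mats: GraphMatrices | None = None,
    orbits: OrbitPartition | None = None,
) -> dict[str, float]:
    """All ten entropy descriptors keyed by ``ENTROPY_DESCRIPTOR_NAMES``."""
    if orbits is None:
        orbits = automorphism_orbits(g)
    parts = partition_entropies(g, mats)
    values = {
        "dehmer_fV": dehmer_entropy(g, FunctionalKind.fV_centrality),
        "topological_info_content": topological_info_content(g, orbits),
        "vertex_complexity": parts.vertex_complexity,
        "info_distance_degree": parts.info_distance_degree,
        "info_edge_equality": parts.info_edge_equality,
        "balaban_J": balaban_J(g, mats),
        "symmetry_index": symmetry_index(g, orbits),
        "bonchev_ID": parts.bonchev_ID,
        "dehmer_fP": dehmer_entropy(g, FunctionalKind.fP_spheres),
        "bonchev_IDW": parts.bonchev_IDW,
    }
    return {k: values[k] for k in ENTROPY_DESCRIPTOR_NAMES}
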