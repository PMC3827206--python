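from __future__ import annotations

import networkx as nx
import pytest

from structmark.graph_core import Graph


def path_graph(labels: str | list[str]) -> Graph:
    labels = list(labels)
    return Graph.from_edges(list(zip(labels, labels[1:])))


def cycle_graph(n: int) -> Graph:
    labels = [f"v{i}" for i in range(n)]
    return Graph.from_edges(
        [(labels[i], labels[(i + 1) % n]) for i in range(n)]
    )


def complete_graph(n: int) -> Graph:
    labels = [f"v{i}" for i in range(n)]
    return Graph.from_edges(
        [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]
    )


def empty_graph(n: int) -> Graph:
    return Graph.from_edges([], vertices=[f"v{i}" for i in range(n)])


def star_graph(n_leaves: int) -> Graph:
    return Graph.from_edges([("c", f"l{i}") for i in range(n_leaves)])


@pytest.fixture
def k2() -> Graph:
    return Graph.from_edges([("a", "b")])


@pytest.fixture
def p3() -> Graph:
    return path_graph("abc")


@pytest.fixture
def p4() -> Graph:
    return path_graph("abcd")


@pytest.fixture
def k3() -> Graph:
    return complete_graph(3)


@pytest.fixture
def k4() -> Graph:
    return complete_graph(4)


@pytest.fixture
def c4() -> Graph:
    return cycle_graph(4)


@pytest.fixture
def c6() -> Graph:
    return cycle_graph(6)


@pytest.fixture
def star4(
) -> Graph:  # K_{1,3}
    return star_graph(3)


@pytest.fixture
def asymmetric6() -> Graph:
    """Smallest asymmetric graph: triangle with pendant paths of lengths
    1 and 2 on two of its corners (6 vertices, 6 edges, |Aut| = 1)."""
    return Graph.from_edges(
        [("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e"),
         ("b", "f")]
    )


@pytest.fixture
def two_disjoint_edges() -> Graph:
    return Graph.from_edges([("a", "b"), ("c", "d")])


def connected_atlas_graphs(max_n: int = 6, min_n: int = 2) -> list[Graph]:
    """All connected graphs with min_n <= n <= max_n (from the atlas)."""
    out = []
    for ag in nx.graph_atlas_g():
        n = ag.number_of_nodes()
        if n < min_n or n > max_n:
            continue
        if not nx.is_connected(ag):
            continue
        relabelled = nx.relabel_nodes(ag, {i: f"v{i}" for i in ag.nodes()})
        out.append(Graph.from_networkx(relabelled))
    return out
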