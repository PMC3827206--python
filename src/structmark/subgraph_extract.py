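"""Gene-set-driven subgraph extraction (GO-term surrogate).

Each named gene set induces one vertex-induced subgraph per condition
network; subgraphs with fewer present genes than ``min_genes`` are
dropped. Gene sets travel in GMT format (name, description, then
tab-separated gene IDs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .graph_core import Graph, read_edge_list, write_edge_list

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "extract_term_subgraphs",
    "write_subgraph_dir",
    "read_subgraph_dir",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered, named gene sets with a namespace tag."""

    sets: tuple[tuple[str, tuple[str, ...]], ...]
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        names = [name for name, _ in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names")
        for name, genes in self.sets:
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, Iterable[str]],
        namespace: str = "biological_process",
    ) -> "GeneSetCollection":
        return cls(
            sets=tuple(
                (str(k), tuple(str(g) for g in v)) for k, v in mapping.items()
            ),
            namespace=namespace,
        )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.namespace, *genes]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets = []
    namespace = "biological_process"
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, namespace, *genes = parts
        sets.append((name, tuple(genes)))
    return GeneSetCollection(sets=tuple(sets), namespace=namespace)


def extract_term_subgraphs(
    g: Graph, sets: GeneSetCollection, min_genes: int = 5
) -> list[tuple[str, Graph]]:
    """Vertex-induced subgraph of *g* for each gene set, in input order.

    A subgraph is kept only when at least *min_genes* of the set's genes
    are present in *g*; induced subgraphs may be disconnected (handled
    downstream by the largest-component rule).
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    vertex_set = set(g.vertex_ids)
    out: list[tuple[str, Graph]] = []
    for name, genes in sets:
        present = set(genes) & vertex_set
        if len(present) < min_genes:
            continue
        out.append((name, g.induced_subgraph(present)))
    return out


def write_subgraph_dir(
    subgraphs: Iterable[tuple[str, Graph]],
    condition: str,
    out_dir: str | Path,
) -> list[Path]:
    """Write each subgraph as <condition>__<term>.txt edge lists with a
    .vertices sidecar (isolated vertices are meaningful)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, sub in subgraphs:
        path = out_dir / f"{condition}__{name}.txt"
        write_edge_list(sub, path, vertices_path=path.with_suffix(".vertices"))
        paths.append(path)
    return paths


def read_subgraph_dir(path: str | Path) -> list[tuple[str, str, Graph]]:
    """Read (condition, term, graph) triples written by
    :func:`write_subgraph_dir`, sorted by filename."""
    out = []
    for p in sorted(Path(path).glob("*.txt")):
        cond, _, term = p.stem.partition("__")
        sidecar = p.with_suffix(".vertices")
        g = read_edge_list(p, vertices_path=sidecar if sidecar.exists() else None)
        out.append((cond, term, g))
    return out
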