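"""Seeded generators for every input the pipeline consumes.

Three generators:

- :func:`simulate_expression` — two-condition genes × samples matrices
  with planted equicorrelated modules (membership partially rewired
  between conditions, so the inferable network topology differs) and
  mean-shifted differentially expressed genes for the biomarker arm.
- :func:`simulate_gene_sets` — overlapping gene sets of varying size, a
  configurable fraction aligned with planted modules (GO surrogate).
- :func:`simulate_graph_classes` — two-class Erdős–Rényi graph
  populations that isolate the measures → classification path from
  inference.

Every generator is bit-reproducible given its seed and returns (or
embeds) a truth record naming the planted structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_core import Graph
from .subgraph_extract import GeneSetCollection

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_graph_classes",
    "er_graph",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic two-condition benchmark."""

    n_genes: int = 200
    n_samples_per_condition: int = 50
    n_modules: int = 10
    module_size: int = 5
    within_module_correlation: tuple[float, float] = (0.9, 0.9)
    module_rewire_fraction: float = 0.5
    n_de_genes: int = 10
    de_effect_size: float = 2.0
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (5, 20)
    module_aligned_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples_per_condition, self.n_modules,
               self.module_size, self.n_gene_sets) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit into the gene universe")
        for rho in self.within_module_correlation:
            if not 0.0 <= rho < 1.0:
                raise ValueError("correlations must lie in [0, 1)")
        if not 0.0 <= self.module_rewire_fraction <= 1.0:
            raise ValueError("module_rewire_fraction must lie in [0, 1]")
        if not 0.0 <= self.module_aligned_fraction <= 1.0:
            raise ValueError("module_aligned_fraction must lie in [0, 1]")
        lo, hi = self.gene_set_size_range
        if not 2 <= lo <= hi <= self.n_genes:
            raise ValueError("gene_set_size_range outside [2, n_genes]")
        if self.n_de_genes > self.n_genes:
            raise ValueError("more DE genes than genes")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def _module_map(
    genes: list[str], cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, int]]:
    """Benign and cancer module membership maps (gene -> module index).

    Benign modules take the first n_modules*module_size genes in blocks.
    The cancer map starts identical and then swaps a rewire fraction of
    module genes with unassigned (noise) genes, changing which genes are
    co-regulated without changing module sizes.
    """
    benign: dict[str, int] = {}
    for mod in range(cfg.n_modules):
        for j in range(cfg.module_size):
            benign[genes[mod * cfg.module_size + j]] = mod
    cancer = dict(benign)
    noise = [g for g in genes if g not in benign]
    module_genes = sorted(benign)
    n_swap = int(round(cfg.module_rewire_fraction * len(module_genes)))
    n_swap = min(n_swap, len(noise))
    if n_swap:
        out_genes = rng.choice(module_genes, size=n_swap, replace=False)
        in_genes = rng.choice(noise, size=n_swap, replace=False)
        for g_out, g_in in zip(out_genes, in_genes):
            cancer[g_in] = cancer.pop(g_out)
    return benign, cancer


def _sample_condition(
    genes: list[str],
    module_map: dict[str, int],
    rho: float,
    n_samples: int,
    n_modules: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Equicorrelated Gaussian blocks: gene value =
    sqrt(rho)·Z_module + sqrt(1−rho)·eps; noise genes are pure eps."""
    shared = rng.standard_normal((n_modules, n_samples))
    eps = rng.standard_normal((len(genes), n_samples))
    x = np.sqrt(1.0 - rho) * eps
    for i, g in enumerate(genes):
        mod = module_map.get(g)
        if mod is None:
            x[i] = eps[i]
        else:
            x[i] += np.sqrt(rho) * shared[mod]
    return x


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """(benign frame, cancer frame, truth record).

    Frames are genes × samples. DE genes receive a +de_effect_size mean
    shift (in within-gene SD units, which is 1 by construction) in the
    cancer condition only. The truth record lists both module maps, the
    DE genes, and the planted within-module pairs per condition.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids()
    benign_map, cancer_map = _module_map(genes, cfg, rng)
    rho_b, rho_c = cfg.within_module_correlation

    xb = _sample_condition(
        genes, benign_map, rho_b, cfg.n_samples_per_condition,
        cfg.n_modules, rng,
    )
    xc = _sample_condition(
        genes, cancer_map, rho_c, cfg.n_samples_per_condition,
        cfg.n_modules, rng,
    )
    de_genes = sorted(
        rng.choice(genes, size=cfg.n_de_genes, replace=False).tolist()
    )
    de_idx = [genes.index(g) for g in de_genes]
    xc[de_idx] += cfg.de_effect_size

    nb = cfg.n_samples_per_condition
    benign = pd.DataFrame(
        xb, index=genes, columns=[f"B{i+1:03d}" for i in range(nb)]
    )
    cancer = pd.DataFrame(
        xc, index=genes, columns=[f"C{i+1:03d}" for i in range(nb)]
    )

    def pairs(mmap: dict[str, int]) -> list[list[str]]:
        mods: dict[int, list[str]] = {}
        for g, m in mmap.items():
            mods.setdefault(m, []).append(g)
        out = []
        for m in sorted(mods):
            members = sorted(mods[m])
            out += [[a, b] for i, a in enumerate(members)
                    for b in members[i + 1:]]
        return out

    truth = {
        "config": asdict(cfg),
        "module_map_benign": benign_map,
        "module_map_cancer": cancer_map,
        "de_genes": de_genes,
        "within_module_pairs_benign": pairs(benign_map),
        "within_module_pairs_cancer": pairs(cancer_map),
    }
    return benign, cancer, truth


def simulate_gene_sets(
    cfg: SimulationConfig, truth: dict | None = None
) -> GeneSetCollection:
    """Overlapping gene sets; a module-aligned fraction each contain one
    whole planted (benign-map) module. Deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed + 1)
    genes = np.array(cfg.gene_ids())
    if truth is not None:
        benign_map = truth["module_map_benign"]
    else:
        benign_map, _ = _module_map(
            list(genes), cfg, np.random.default_rng(cfg.seed)
        )
    modules: dict[int, list[str]] = {}
    for g, m in benign_map.items():
        modules.setdefault(int(m), []).append(g)
    lo, hi = cfg.gene_set_size_range
    n_aligned = int(round(cfg.module_aligned_fraction * cfg.n_gene_sets))
    width = len(str(cfg.n_gene_sets))
    sets = {}
    for k in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        if k < n_aligned:
            mod = int(rng.integers(cfg.n_modules))
            members = sorted(modules[mod])
            size = max(size, len(members))  # aligned sets keep whole module
        pool = np.setdiff1d(genes, np.array(members, dtype=genes.dtype))
        extra = rng.choice(pool, size=size - len(members), replace=False)
        sets[f"SET{k+1:0{width}d}"] = sorted(members + extra.tolist())
    return GeneSetCollection.from_mapping(sets)


def er_graph(
    n_vertices: int, density: float, rng: np.random.Generator,
    prefix: str = "v",
) -> Graph:
    """Erdős–Rényi G(n, p) with zero-padded string labels."""
    width = len(str(n_vertices))
    labels = [f"{prefix}{i:0{width}d}" for i in range(1, n_vertices + 1)]
    edges = []
    for i in range(n_vertices):
        for j in range(i + 1, n_vertices):
            if rng.random() < density:
                edges.append((labels[i], labels[j]))
    return Graph.from_edges(edges, vertices=labels)


def simulate_graph_classes(
    n_per_class: int,
    n_vertices: int,
    class_a_density: float,
    class_b_density: float,
    seed: int = 0,
) -> list[tuple[str, str, Graph]]:
    """Two-class ER populations as (row_id, class_label, graph) triples."""
    for p in (class_a_density, class_b_density):
        if not 0.0 < p < 1.0:
            raise ValueError("densities must lie in (0, 1)")
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str, Graph]] = []
    for label, p in (("A", class_a_density), ("B", class_b_density)):
        for k in range(n_per_class):
            out.append(
                (f"{label}{k+1:04d}", label, er_graph(n_vertices, p, rng))
            )
    return out


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
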