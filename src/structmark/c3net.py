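"""Conservative causal-core (C3NET) network inference.

Pipeline: estimate all pairwise mutual informations, build a pooled null
distribution by permuting one member of randomly chosen gene pairs, keep
MI values above the (1 − alpha) empirical null quantile, then let every
gene contribute at most one edge — the one to its maximum-MI significant
partner. The union of these per-gene picks, undirected and de-duplicated,
is the inferred network, so the edge count never exceeds the gene count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_core import Graph

__all__ = [
    "MIMatrix",
    "mutual_information",
    "mi_matrix",
    "infer_c3net",
    "read_expression",
    "write_expression",
]

_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class MIMatrix:
    """Pairwise MI values (nats) and the significance mask."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    significance_mask: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.gene_ids
        )


def _gaussian_mi_from_r(r: np.ndarray) -> np.ndarray:
    r = np.clip(r, -_CLIP, _CLIP)
    return -0.5 * np.log(1.0 - r * r)


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    estimator: str = "gaussian",
    bins: int = 10,
) -> float:
    """Mutual information between two samples, in nats.

    ``gaussian``: −½ ln(1 − r²) with the sample correlation clipped to
    |r| ≤ 1 − 1e-12 (exact for bivariate normals). ``binned``: plug-in
    estimate on an equal-width 2-D histogram with *bins* bins per axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if estimator == "gaussian":
        r = float(np.corrcoef(x, y)[0, 1])
        return float(_gaussian_mi_from_r(np.asarray(r)))
    if estimator == "binned":
        joint, _, _ = np.histogram2d(x, y, bins=bins)
        joint /= joint.sum()
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        outer = np.outer(px, py)
        return float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())
    raise ValueError(f"unknown estimator {estimator!r}")


def mi_matrix(
    expr: pd.DataFrame, estimator: str = "gaussian", bins: int = 10
) -> np.ndarray:
    """Symmetric MI matrix (zero diagonal) for a genes × samples frame."""
    x = expr.to_numpy(dtype=float)
    if (x.std(axis=1) == 0).any():
        bad = expr.index[x.std(axis=1) == 0].tolist()
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    if estimator == "gaussian":
        mi = _gaussian_mi_from_r(np.corrcoef(x))
    elif estimator == "binned":
        n = x.shape[0]
        mi = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mi[i, j] = mi[j, i] = mutual_information(
                    x[i], x[j], estimator="binned", bins=bins
                )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    np.fill_diagonal(mi, 0.0)
    return (mi + mi.T) / 2.0  # exact symmetry


def infer_c3net(
    expr: pd.DataFrame,
    estimator: str = "gaussian",
    alpha: float = 0.05,
    n_permutations: int = 100,
    seed: int = 0,
    bins: int = 10,
    return_mi: bool = False,
) -> Graph | tuple[Graph, MIMatrix]:
    """Infer a C3NET network from a genes × samples expression frame.

    Parameters
    ----------
    expr
        Genes × samples matrix; index holds gene IDs.
    estimator
        ``gaussian`` (default) or ``binned``.
    alpha
        Significance level for the pooled permutation null; must lie in
        (0, 1).
    n_permutations
        Size of the pooled null sample (one shuffled pair each).
    seed
        Seed for the permutation RNG — output is deterministic given it.
    return_mi
        Also return the :class:`MIMatrix` (for ``--emit-mi``).

    Returns
    -------
    Graph with all genes as vertices (isolated genes kept) and at most one
    edge contributed per gene. Argmax ties break toward the
    lexicographically smallest partner ID.
    """
    n_genes, n_samples = expr.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    genes = [str(g) for g in expr.index]
    mi = mi_matrix(expr, estimator=estimator, bins=bins)

    rng = np.random.default_rng(seed)
    x = expr.to_numpy(dtype=float)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        i, j = rng.choice(n_genes, size=2, replace=False)
        null[k] = mutual_information(
            rng.permutation(x[i]), x[j], estimator=estimator, bins=bins
        )
    threshold = float(np.quantile(null, 1.0 - alpha))

    mask = mi > threshold
    np.fill_diagonal(mask, False)

    edges: set[tuple[str, str]] = set()
    for i in range(n_genes):
        sig = np.flatnonzero(mask[i])
        if sig.size == 0:
            continue
        best = mi[i, sig].max()
        # argmax tie-break: lexicographically smallest partner ID
        partner = min(genes[j] for j in sig if mi[i, j] == best)
        u, v = sorted((genes[i], partner))
        edges.add((u, v))
    graph = Graph.from_edges(edges, vertices=genes)
    if return_mi:
        return graph, MIMatrix(
            gene_ids=tuple(genes),
            values=mi,
            significance_mask=mask,
            threshold=threshold,
        )
    return graph


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × samples TSV with a header row of sample IDs and gene IDs in
    the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")
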