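"""Descriptor degeneracy (ndv) and discrimination-power reporting.

``ndv`` counts the networks in a population whose descriptor value is not
unique — i.e. shared, within tolerance, with at least one other network.
Equality groups are the single-linkage (transitive) closure of the
pairwise tolerance relation, so ndv is either 0 or at least 2.

``uniqueness_report`` tabulates ndv (absolute, relative) plus the
Konstantinova sensitivity (N − ndv)/N per descriptor, for the pooled
population and each subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .features_classify import FeatureTable
from .graph_core import Graph, assert_non_isomorphic

__all__ = ["ndv", "UniquenessReport", "uniqueness_report"]


def _collision_groups(values: np.ndarray, tol: float) -> np.ndarray:
    """Group label per entry under the single-linkage closure of
    |a − b| <= tol * max(|a|, |b|)."""
    n = values.size
    if n == 0:
        return np.zeros(0, dtype=int)
    order = np.argsort(values, kind="stable")
    v = values[order]
    rows, cols = [], []
    # sorted sweep over explicit pairs; relative tolerance is not monotone
    # along the sweep, so each candidate is checked, with an early break
    # once no later (larger-gap) value can still satisfy the relation
    absmax_tail = np.maximum.accumulate(np.abs(v)[::-1])[::-1]
    for i in range(n):
        for j in range(i + 1, n):
            gap = v[j] - v[i]
            if gap == 0.0 or gap <= tol * max(abs(v[i]), abs(v[j])):
                rows.append(i)
                cols.append(j)
            elif gap > tol * max(abs(v[i]), absmax_tail[j]):
                break
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    _, labels_sorted = connected_components(adj, directed=False)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def ndv(values: Sequence[float], tol: float = 0.0) -> int:
    """Number of entries whose value collides with at least one other.

    Collision = equality within relative tolerance *tol*, closed under
    single linkage. ``ndv`` is never 1: a collision involves >= 2 entries.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    arr = np.asarray(values, dtype=float)
    labels = _collision_groups(arr, tol)
    counts = np.bincount(labels)
    return int(counts[labels][counts[labels] >= 2].size)


@dataclass(frozen=True)
class UniquenessReport:
    """Per-descriptor, per-group degeneracy table."""

    table: pd.DataFrame          # index: descriptor; MultiIndex columns
    group_sizes: dict[str, int]
    tol: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def uniqueness_report(
    tables: Mapping[str, FeatureTable | pd.DataFrame],
    tol: float = 1e-10,
    graphs: Mapping[str, Sequence[Graph]] | None = None,
    pooled_name: str = "all",
) -> UniquenessReport:
    """ndv/sensitivity per descriptor for the pooled set and each group.

    Parameters
    ----------
    tables
        Group name -> descriptor matrix (rows = networks, columns =
        descriptors). All groups must share the same columns.
    tol
        Relative tolerance for value collisions (default 1e-10 — exact
        equality would understate degeneracy of analytically equal values
        computed along different code paths).
    graphs
        Optional group name -> graphs, aligned with table rows. When
        given, each group is verified pairwise non-isomorphic; duplicates
        raise ``ValueError``.
    """
    frames: dict[str, pd.DataFrame] = {}
    for name, t in tables.items():
        frames[name] = t.values if isinstance(t, FeatureTable) else t
    cols = None
    for name, df in frames.items():
        if cols is None:
            cols = list(df.columns)
        elif list(df.columns) != cols:
            raise ValueError("groups have mismatched descriptor columns")
    if cols is None:
        raise ValueError("no groups given")
    if graphs is not None:
        for name, gs in graphs.items():
            assert_non_isomorphic(gs, group=name)

    pooled = pd.concat(list(frames.values()), axis=0)
    groups: dict[str, pd.DataFrame] = {pooled_name: pooled, **frames}

    rows = {}
    for desc in cols:
        row = {}
        for gname, df in groups.items():
            count = ndv(df[desc].to_numpy(dtype=float), tol)
            size = len(df)
            row[("ndv_absolute", gname)] = count
            row[("ndv_relative", gname)] = count / size if size else 0.0
            row[("sensitivity", gname)] = (
                (size - count) / size if size else 1.0
            )
        rows[desc] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    order = ["ndv_absolute", "ndv_relative", "sensitivity"]
    table = table[[c for stat in order for c in table.columns
                   if c[0] == stat]]
    sizes = {name: len(df) for name, df in groups.items()}
    return UniquenessReport(table=table, group_sizes=sizes, tol=tol)
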