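"""Feature tables, information-gain selection, and polynomial-SVM CV.

Two arms share this machinery: the structural arm (networks × graph
descriptors) and the conventional arm (samples × gene expression). Both
go through information-gain top-k selection and an exhaustively
grid-searched polynomial-kernel SVM under stratified k-fold CV.

Feature selection and z-scoring are refit inside each training fold —
never on held-out rows — and metrics are macro-averaged over the two
classes, which makes sensitivity, specificity and recall coincide on any
binary confusion matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .entropy import ENTROPY_DESCRIPTOR_NAMES, entropy_descriptors
from .graph_core import Graph, automorphism_orbits, build_matrices
from .spectral import SPECTRAL_DESCRIPTOR_NAMES, spectral_descriptors

__all__ = [
    "FeatureTable",
    "CVReport",
    "DEFAULT_GRID",
    "METRIC_NAMES",
    "information_gain",
    "information_gain_scores",
    "select_top_k",
    "binary_macro_metrics",
    "cross_validated_svm",
    "descriptor_table",
]

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "precision",
    "recall",
    "accuracy",
    "f_score",
)

#: Exhaustive polynomial-SVM grid: degree, cost, kernel coefficient.
DEFAULT_GRID: dict[str, tuple] = {
    "degree": (1, 2, 3, 4),
    "C": (0.1, 1.0, 10.0, 100.0),
    "gamma": (0.001, 0.01, 0.1, 1.0),
}


@dataclass(frozen=True)
class FeatureTable:
    """Rows × features matrix with a binary class label per row.

    Rows containing non-finite values are dropped at construction and
    recorded in ``dropped_rows``.
    """

    values: pd.DataFrame
    labels: pd.Series
    dropped_rows: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels have different row indices")
        bad = ~np.isfinite(self.values.to_numpy(dtype=float)).all(axis=1)
        if bad.any():
            dropped = tuple(str(r) for r in self.values.index[bad])
            object.__setattr__(self, "values", self.values.loc[~bad])
            object.__setattr__(self, "labels", self.labels.loc[~bad])
            object.__setattr__(
                self, "dropped_rows", self.dropped_rows + dropped
            )
        classes = self.labels.unique()
        if len(classes) != 2:
            raise ValueError(
                f"need exactly 2 classes, got {sorted(map(str, classes))}"
            )

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            values=self.values[list(names)], labels=self.labels
        )


@dataclass(frozen=True)
class CVReport:
    """Per-fold and aggregate classification error measures."""

    folds: pd.DataFrame            # one row per fold: metrics + params
    mean: pd.Series                # metric means over folds
    std_error: pd.Series           # sample SD / sqrt(folds)
    chosen_params: tuple[dict, ...]

    def to_dict(self) -> dict:
        return {
            "metrics": {
                m: {
                    "mean": float(self.mean[m]),
                    "sd_error": float(self.std_error[m]),
                }
                for m in METRIC_NAMES
            },
            "per_fold": self.folds[list(METRIC_NAMES)].to_dict("records"),
            "chosen_params": list(self.chosen_params),
        }


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize by equal-frequency quantile edges (ties merge bins)."""
    qs = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(qs)[1:-1]
    return np.searchsorted(edges, x, side="right")


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def information_gain(
    feature: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """H(labels) − H(labels | feature binned equal-frequency), in bits."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("labels are constant")
    x = np.asarray(feature, dtype=float)
    b = _equal_frequency_bins(x, n_bins)
    h_y = _entropy_bits(np.bincount(y))
    h_cond = 0.0
    n = len(y)
    for v in np.unique(b):
        in_bin = b == v
        h_cond += in_bin.sum() / n * _entropy_bits(np.bincount(y[in_bin]))
    return h_y - h_cond


def information_gain_scores(
    table: FeatureTable, n_bins: int = 10
) -> pd.Series:
    labels = table.labels.to_numpy()
    scores = {
        name: information_gain(
            table.values[name].to_numpy(dtype=float), labels, n_bins
        )
        for name in table.feature_names
    }
    return pd.Series(scores)


def _top_k_names(
    values: np.ndarray,
    labels: np.ndarray,
    names: Sequence[str],
    k: int,
    n_bins: int,
) -> list[str]:
    scores = [
        information_gain(values[:, j], labels, n_bins)
        for j in range(values.shape[1])
    ]
    # highest gain first; exact ties broken by feature-name order
    ranked = sorted(zip(scores, names), key=lambda t: (-t[0], t[1]))
    return [name for _, name in ranked[:k]]


def select_top_k(table: FeatureTable, k: int, n_bins: int = 10) -> FeatureTable:
    """Keep the k features with highest information gain (ties by name)."""
    if k > len(table.feature_names):
        raise ValueError("k exceeds feature count")
    names = _top_k_names(
        table.values.to_numpy(dtype=float),
        table.labels.to_numpy(),
        table.feature_names,
        k,
        n_bins,
    )
    return table.subset_features(names)


def binary_macro_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> dict[str, float]:
    """Six error measures, macro-averaged over the two classes.

    Each class plays the positive role once and per-class values are
    averaged; this forces sensitivity = specificity = recall.
    """
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValueError("need two classes in y_true")
    per_class = {m: [] for m in ("sensitivity", "specificity", "precision",
                                 "recall", "f_score")}
    for pos in classes:
        tp = float(((y_true == pos) & (y_pred == pos)).sum())
        fn = float(((y_true == pos) & (y_pred != pos)).sum())
        tn = float(((y_true != pos) & (y_pred != pos)).sum())
        fp = float(((y_true != pos) & (y_pred == pos)).sum())
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        per_class["sensitivity"].append(sens)
        per_class["specificity"].append(spec)
        per_class["precision"].append(prec)
        per_class["recall"].append(sens)
        per_class["f_score"].append(f)
    out = {m: float(np.mean(v)) for m, v in per_class.items()}
    out["accuracy"] = float((y_true == y_pred).mean())
    return {m: out[m] for m in METRIC_NAMES}


def _zscore_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _grid_iter(grid: Mapping[str, Sequence]) -> list[dict]:
    keys = ("degree", "C", "gamma")
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]


def cross_validated_svm(
    table: FeatureTable,
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 10,
    seed: int = 0,
    select_k: int | None = None,
    inner_folds: int = 3,
    n_bins: int = 10,
) -> CVReport:
    """Stratified k-fold CV of a polynomial-kernel SVM with per-fold
    information-gain selection and exhaustive inner grid search.

    Parameters
    ----------
    table
        Feature table with binary labels; each class must have at least
        *folds* members.
    grid
        Mapping with ``degree``, ``C`` and ``gamma`` sequences
        (:data:`DEFAULT_GRID` when omitted).
    select_k
        When set, the top-k information-gain features are re-selected
        inside each training fold (no leakage into held-out rows).
    inner_folds
        Stratified folds of the inner accuracy estimate used to pick grid
        points; ties go to the first point in deterministic grid order.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y_all = table.labels.to_numpy()
    counts = pd.Series(y_all).value_counts()
    if (counts < folds).any():
        raise ValueError("each class must have at least `folds` members")
    x_all = table.values.to_numpy(dtype=float)
    names = table.feature_names
    combos = _grid_iter(grid)

    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    chosen: list[dict] = []
    for fold_idx, (tr, te) in enumerate(outer.split(x_all, y_all)):
        x_tr, y_tr = x_all[tr], y_all[tr]
        x_te, y_te = x_all[te], y_all[te]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise ValueError(f"degenerate fold {fold_idx}: single class")
        if select_k is not None:
            keep = _top_k_names(x_tr, y_tr, names, select_k, n_bins)
            cols = [names.index(c) for c in keep]
            x_tr, x_te = x_tr[:, cols], x_te[:, cols]
        mu, sd = _zscore_fit(x_tr)
        x_tr = (x_tr - mu) / sd
        x_te = (x_te - mu) / sd

        best_acc, best = -1.0, combos[0]
        inner = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=seed + fold_idx + 1
        )
        inner_splits = list(inner.split(x_tr, y_tr))
        for params in combos:
            accs = []
            for itr, ite in inner_splits:
                clf = SVC(kernel="poly", coef0=1.0, **params)
                clf.fit(x_tr[itr], y_tr[itr])
                accs.append(float((clf.predict(x_tr[ite]) == y_tr[ite]).mean()))
            acc = float(np.mean(accs))
            if acc > best_acc:
                best_acc, best = acc, params
        clf = SVC(kernel="poly", coef0=1.0, **best)
        clf.fit(x_tr, y_tr)
        metrics = binary_macro_metrics(y_te, clf.predict(x_te))
        rows.append({**metrics, **{f"param_{k}": v for k, v in best.items()}})
        chosen.append(dict(best))

    folds_df = pd.DataFrame(rows)
    mean = folds_df[list(METRIC_NAMES)].mean()
    sd = folds_df[list(METRIC_NAMES)].std(ddof=1).fillna(0.0)
    std_error = sd / np.sqrt(folds)
    return CVReport(
        folds=folds_df, mean=mean, std_error=std_error,
        chosen_params=tuple(chosen),
    )


def descriptor_frame(
    labelled_graphs: Sequence[tuple[str, str, Graph]],
    battery: Sequence[str] = ("eigenvalue", "entropy"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw descriptor matrix and labels, without class-count validation.

    Graphs on which a descriptor is undefined yield all-NaN rows (kept
    here; :class:`FeatureTable` drops them).
    """
    unknown = set(battery) - {"eigenvalue", "entropy"}
    if unknown:
        raise ValueError(f"unknown battery component(s): {sorted(unknown)}")
    records = {}
    labels = {}
    for row_id, label, g in labelled_graphs:
        # e.g. no component with >= 2 vertices -> all-NaN row
        try:
            mats = build_matrices(g)
            row: dict[str, float] = {}
            if "eigenvalue" in battery:
                row.update(spectral_descriptors(mats).values)
            if "entropy" in battery:
                orbits = automorphism_orbits(g)
                row.update(entropy_descriptors(g, mats, orbits))
        except ValueError:
            row = {}
        records[row_id] = row
        labels[row_id] = label
    columns = []
    if "eigenvalue" in battery:
        columns += list(SPECTRAL_DESCRIPTOR_NAMES)
    if "entropy" in battery:
        columns += list(ENTROPY_DESCRIPTOR_NAMES)
    # reindex restores all-NaN rows for graphs whose computation failed
    values = pd.DataFrame.from_dict(records, orient="index").reindex(
        index=list(records), columns=columns
    )
    return values, pd.Series(labels)


def descriptor_table(
    labelled_graphs: Sequence[tuple[str, str, Graph]],
    battery: Sequence[str] = ("eigenvalue", "entropy"),
) -> FeatureTable:
    """Assemble a two-class FeatureTable of structural descriptors.

    Parameters
    ----------
    labelled_graphs
        (row_id, class_label, graph) triples.
    battery
        Any subset of {"eigenvalue", "entropy"}; columns keep the stable
        battery order (eigenvalue columns first).
    """
    values, labels = descriptor_frame(labelled_graphs, battery)
    return FeatureTable(values=values, labels=labels)
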