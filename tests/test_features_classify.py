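from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structmark.features_classify import (
    FeatureTable,
    binary_macro_metrics,
    cross_validated_svm,
    descriptor_table,
    information_gain,
    information_gain_scores,
    select_top_k,
)
from structmark.synthetic_data import simulate_graph_classes

from tests import oracles

SMALL_GRID = {"degree": (1, 2), "C": (1.0, 10.0), "gamma": (0.01, 0.1)}


def _table(x: np.ndarray, labels, names=None) -> FeatureTable:
    names = names or [f"f{i:03d}" for i in range(x.shape[1])]
    values = pd.DataFrame(x, columns=names)
    return FeatureTable(
        values=values, labels=pd.Series(list(labels), index=values.index)
    )


class TestFeatureTable:
    def test_nan_rows_dropped_and_logged(self):
        x = np.ones((4, 2))
        x[2, 1] = np.nan
        t = _table(x, ["a", "a", "b", "b"])
        assert t.n_rows == 3
        assert t.dropped_rows == ("2",)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            _table(np.ones((3, 2)), ["a", "a", "a"])


class TestInformationGain:
    def test_perfect_feature(self):
        y = np.array([0] * 50 + [1] * 50)
        x = y.astype(float)
        assert information_gain(x, y, 2) == pytest.approx(1.0)

    def test_bins_separate_classes(self):
        assert information_gain(
            np.array([1.0, 2.0, 9.0, 10.0]), np.array([0, 0, 1, 1]), 2
        ) == pytest.approx(1.0)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        y = rng.integers(0, 2, 1000)
        assert information_gain(x, y, 10) <= 0.05

    def test_constant_labels_raise(self):
        with pytest.raises(ValueError, match="constant"):
            information_gain(np.arange(10.0), np.zeros(10), 2)

    def test_n_bins_validated(self):
        with pytest.raises(ValueError, match="n_bins"):
            information_gain(np.arange(4.0), np.array([0, 0, 1, 1]), 1)

    def test_scores_series_matches_per_column(self):
        rng = np.random.default_rng(12)
        t = _table(rng.standard_normal((30, 3)), ["a", "b"] * 15)
        scores = information_gain_scores(t, n_bins=5)
        for name in t.feature_names:
            assert scores[name] == pytest.approx(information_gain(
                t.values[name].to_numpy(), t.labels.to_numpy(), 5
            ))

    def test_non_negative_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal(60)
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            ig = information_gain(x, y, 5)
            assert -1e-12 <= ig <= 1.0 + 1e-12


class TestSelectTopK:
    def test_identity_when_k_is_feature_count(self):
        t = _table(np.random.default_rng(2).standard_normal((20, 4)),
                   ["a", "b"] * 10)
        got = select_top_k(t, 4)
        assert set(got.feature_names) == set(t.feature_names)

    def test_informative_feature_wins(self):
        rng = np.random.default_rng(3)
        y = np.array(["a"] * 30 + ["b"] * 30)
        x = rng.standard_normal((60, 10))
        x[:, 7] = (y == "b").astype(float) + 0.01 * rng.standard_normal(60)
        t = _table(x, y)
        got = select_top_k(t, 1)
        assert got.feature_names == ["f007"]

    def test_tie_broken_by_name(self):
        y = np.array([0, 0, 1, 1] * 5)
        x = np.column_stack([y, y]).astype(float)
        t = _table(x, y, names=["zeta", "alpha"])
        got = select_top_k(t, 1)
        assert got.feature_names == ["alpha"]

    def test_k_too_large(self):
        t = _table(np.random.default_rng(4).standard_normal((10, 3)),
                   ["a", "b"] * 5)
        with pytest.raises(ValueError, match="k exceeds"):
            select_top_k(t, 4)


class TestMacroMetrics:
    def test_symmetric_confusion(self):
        y = np.array(["p"] * 10 + ["n"] * 10)
        pred = y.copy()
        pred[8:10] = "n"
        pred[18:20] = "p"
        m = binary_macro_metrics(y, pred)
        for name in ("sensitivity", "specificity", "precision", "recall",
                     "accuracy", "f_score"):
            assert m[name] == pytest.approx(0.8), name

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_confusion_count_oracle(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        y = np.array(["A"] * (tp + fn) + ["B"] * (tn + fp))
        pred = np.array(
            ["A"] * tp + ["B"] * fn + ["B"] * tn + ["A"] * fp
        )
        got = binary_macro_metrics(y, pred)
        want = oracles.oracle_macro_metrics(tp, fn, tn, fp)
        for name, v in want.items():
            assert got[name] == pytest.approx(v), name

    @given(st.integers(1, 30), st.integers(0, 30), st.integers(1, 30),
           st.integers(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_macro_sensitivity_equals_specificity(self, tp, fn, tn, fp):
        y = np.array(["A"] * (tp + fn) + ["B"] * (tn + fp))
        pred = np.array(["A"] * tp + ["B"] * fn + ["B"] * tn + ["A"] * fp)
        m = binary_macro_metrics(y, pred)
        assert m["sensitivity"] == pytest.approx(m["specificity"])
        assert m["recall"] == pytest.approx(m["sensitivity"])


class TestCrossValidatedSVM:
    def test_separable_clusters_perfect(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((30, 3)) + 10
        b = rng.standard_normal((30, 3)) - 10
        t = _table(np.vstack([a, b]), ["a"] * 30 + ["b"] * 30)
        rep = cross_validated_svm(t, grid=SMALL_GRID, folds=5, seed=5)
        assert rep.mean["accuracy"] == pytest.approx(1.0)
        assert rep.std_error["accuracy"] == pytest.approx(0.0)

    def test_aggregate_is_mean_of_folds(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((40, 4))
        t = _table(x, ["a", "b"] * 20)
        rep = cross_validated_svm(t, grid=SMALL_GRID, folds=4, seed=6)
        for m in rep.mean.index:
            assert rep.mean[m] == pytest.approx(
                rep.folds[m].mean(), abs=1e-12
            )
            assert 0.0 <= rep.mean[m] <= 1.0
            assert rep.std_error[m] >= 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((40, 4))
        t = _table(x, ["a", "b"] * 20)
        r1 = cross_validated_svm(t, grid=SMALL_GRID, folds=4, seed=1)
        r2 = cross_validated_svm(t, grid=SMALL_GRID, folds=4, seed=1)
        pd.testing.assert_frame_equal(r1.folds, r2.folds)

    def test_class_count_validated(self):
        t = _table(np.random.default_rng(8).standard_normal((8, 2)),
                   ["a", "b"] * 4)
        with pytest.raises(ValueError, match="folds"):
            cross_validated_svm(t, grid=SMALL_GRID, folds=5, seed=0)

    def test_report_dict_shape(self):
        rng = np.random.default_rng(9)
        t = _table(rng.standard_normal((20, 3)), ["a", "b"] * 10)
        rep = cross_validated_svm(t, grid=SMALL_GRID, folds=2, seed=0)
        d = rep.to_dict()
        assert set(d["metrics"]) == {
            "sensitivity", "specificity", "precision", "recall",
            "accuracy", "f_score",
        }
        assert all({"mean", "sd_error"} <= set(v.keys())
                   for v in d["metrics"].values())
        assert len(d["per_fold"]) == 2
        assert all({"degree", "C", "gamma"} == set(p)
                   for p in d["chosen_params"])


class TestDescriptorTable:
    def test_column_order_and_labels(self):
        graphs = simulate_graph_classes(3, 12, 0.2, 0.5, seed=10)
        t = descriptor_table(graphs, battery=("eigenvalue", "entropy"))
        assert t.values.shape == (6, 21)
        assert t.feature_names[:2] == ["energy", "estrada_index"]
        assert t.feature_names[11] == "dehmer_fV"
        assert sorted(t.labels.unique()) == ["A", "B"]

    def test_unknown_battery(self):
        graphs = simulate_graph_classes(2, 8, 0.3, 0.5, seed=11)
        with pytest.raises(ValueError, match="battery"):
            descriptor_table(graphs, battery=("spectral",))
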