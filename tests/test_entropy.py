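from __future__ import annotations

import math

import numpy as np
import pytest

from structmark.entropy import (
    ENTROPY_DESCRIPTOR_NAMES,
    balaban_J,
    dehmer_entropy,
    entropy_descriptors,
    partition_entropies,
    shannon_entropy,
    symmetry_index,
    topological_info_content,
)
from structmark.graph_core import Graph, automorphism_orbits

from tests import oracles
from tests.conftest import (
    complete_graph,
    connected_atlas_graphs,
    cycle_graph,
)


class TestShannonEntropy:
    def test_degenerate(self):
        assert shannon_entropy([1.0]) == 0.0

    def test_fair_coin(self):
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(1.0)

    def test_two_thirds(self):
        assert shannon_entropy([2 / 3, 1 / 3]) == pytest.approx(
            0.9183, abs=5e-5
        )

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="negative"):
            shannon_entropy([1.5, -0.5])

    def test_rejects_bad_sum(self):
        with pytest.raises(ValueError, match="sum"):
            shannon_entropy([0.5, 0.4])

    def test_zero_times_log_zero(self):
        assert shannon_entropy([1.0, 0.0, 0.0]) == 0.0


class TestDehmerEntropy:
    @pytest.mark.parametrize("factory", [
        lambda: cycle_graph(6), lambda: complete_graph(4),
    ])
    @pytest.mark.parametrize("kind", ["fV_centrality", "fP_spheres"])
    def test_vertex_transitive_maximal(self, factory, kind):
        g = factory()
        assert dehmer_entropy(g, kind) == pytest.approx(math.log2(g.n))

    def test_p3_spheres_preset(self, p3):
        # ends: spheres (1,1), centre: (2,0); c=(2,1) => f=(3,4,3)
        assert dehmer_entropy(p3, "fP_spheres") == pytest.approx(
            oracles.entropy_bits([3, 4, 3])
        )
        assert dehmer_entropy(p3, "fP_spheres") == pytest.approx(
            1.5710, abs=5e-5
        )

    def test_star_closeness(self, star4):
        # closeness (1, 3/5, 3/5, 3/5) => p = (5/14, 3/14, 3/14, 3/14)
        expected = oracles.entropy_bits([5, 3, 3, 3])
        assert dehmer_entropy(star4, "fV_centrality") == pytest.approx(
            expected
        )
        assert expected == pytest.approx(1.9592, abs=5e-5)

    def test_custom_coefficients(self, p3):
        got = dehmer_entropy(p3, "fP_spheres", coefficients=[1.0, 1.0])
        # f = (2, 2, 2): uniform
        assert got == pytest.approx(math.log2(3))

    def test_too_few_coefficients(self, p3):
        with pytest.raises(ValueError, match="coefficients"):
            dehmer_entropy(p3, "fP_spheres", coefficients=[1.0])

    def test_non_positive_coefficients(self, p3):
        with pytest.raises(ValueError, match="positive"):
            dehmer_entropy(p3, "fP_spheres", coefficients=[1.0, 0.0])


class TestTopologicalInfoContent:
    def test_c6_zero(self, c6):
        assert topological_info_content(c6) == 0.0

    def test_p3(self, p3):
        assert topological_info_content(p3) == pytest.approx(
            0.9183, abs=5e-5
        )

    def test_asymmetric_log2n(self, asymmetric6):
        assert topological_info_content(asymmetric6) == pytest.approx(
            math.log2(6)
        )

    def test_zero_iff_vertex_transitive(self):
        for n in (4, 5, 6):
            assert topological_info_content(cycle_graph(n)) == 0.0
            assert topological_info_content(complete_graph(n)) == 0.0
        # paths are not vertex-transitive
        from tests.conftest import path_graph
        assert topological_info_content(path_graph("abcd")) > 0.0


class TestPartitionEntropies:
    def test_complete_graph_trivial_partitions(self, k4):
        pe = partition_entropies(k4)
        assert pe.bonchev_ID == 0.0
        assert pe.info_distance_degree == 0.0

    def test_p3_values(self, p3):
        pe = partition_entropies(p3)
        assert pe.bonchev_ID == pytest.approx(0.9183, abs=5e-5)
        assert pe.bonchev_IDW == pytest.approx(6.0)

    def test_k2_idw_zero(self, k2):
        assert partition_entropies(k2).bonchev_IDW == pytest.approx(0.0)

    def test_matches_oracles_on_atlas(self):
        for g in connected_atlas_graphs(max_n=5):
            pe = partition_entropies(g)
            assert pe.info_distance_degree == pytest.approx(
                oracles.oracle_info_distance_degree(g), abs=1e-9
            )
            assert pe.info_edge_equality == pytest.approx(
                oracles.oracle_info_edge_equality(g), abs=1e-9
            )
            assert pe.bonchev_ID == pytest.approx(
                oracles.oracle_bonchev_ID(g), abs=1e-9
            )
            assert pe.bonchev_IDW == pytest.approx(
                oracles.oracle_bonchev_IDW(g), abs=1e-9
            )
            assert pe.vertex_complexity == pytest.approx(
                oracles.oracle_vertex_complexity(g), abs=1e-9
            )


class TestBalabanJ:
    def test_c6(self, c6):
        assert balaban_J(c6) == pytest.approx(2.0)

    def test_k2(self, k2):
        assert balaban_J(k2) == pytest.approx(1.0)

    def test_p3(self, p3):
        assert balaban_J(p3) == pytest.approx(4 / math.sqrt(6))


class TestSymmetryIndex:
    def test_asymmetric_zero(self, asymmetric6):
        assert symmetry_index(asymmetric6) == 0.0

    def test_k2(self, k2):
        assert symmetry_index(k2) == pytest.approx(2.0)

    def test_c6(self, c6):
        assert symmetry_index(c6) == pytest.approx(
            math.log2(12) + math.log2(6)
        )


class TestDescriptorBattery:
    def test_stable_order(self, p3):
        vals = entropy_descriptors(p3)
        assert tuple(vals) == ENTROPY_DESCRIPTOR_NAMES

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 8
            edges = [
                (f"v{i}", f"v{j}")
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.5
            ]
            g = Graph.from_edges(edges, vertices=[f"v{i}" for i in range(n)])
            perm = rng.permutation(n)
            relab = g.relabel(
                {v: f"w{perm[i]:02d}" for i, v in enumerate(g.vertex_ids)}
            )
            v1 = entropy_descriptors(g)
            v2 = entropy_descriptors(relab)
            for name in ENTROPY_DESCRIPTOR_NAMES:
                assert v1[name] == pytest.approx(
                    v2[name], rel=1e-9, abs=1e-9
                ), name

    def test_entropy_bounds(self):
        for g in connected_atlas_graphs(max_n=5):
            vals = entropy_descriptors(g)
            n = g.n
            assert 0 <= vals["dehmer_fV"] <= math.log2(n) + 1e-9
            assert 0 <= vals["dehmer_fP"] <= math.log2(n) + 1e-9
            assert 0 <= vals["topological_info_content"] <= math.log2(n) + 1e-9
            if g.m:
                assert 0 <= vals["info_edge_equality"] <= math.log2(g.m) + 1e-9
            n_pairs = n * (n - 1) // 2
            assert 0 <= vals["bonchev_ID"] <= math.log2(n_pairs) + 1e-9

    def test_all_ten_match_oracles_on_atlas_n_le_5(self):
        # full n <= 6 sweep lives in the acceptance suite
        for g in connected_atlas_graphs(max_n=5):
            vals = entropy_descriptors(g)
            for name, oracle in oracles.ENTROPY_ORACLES.items():
                assert vals[name] == pytest.approx(
                    oracle(g), abs=1e-9
                ), (name, sorted(g.edges))

    def test_disconnected_uses_largest_component(self):
        g = Graph.from_edges(
            [("a", "b"), ("b", "c"), ("x", "y")]
        )
        comp = Graph.from_edges([("a", "b"), ("b", "c")])
        # distance-based measures must agree with the largest component
        assert balaban_J(g) == pytest.approx(balaban_J(comp))
        assert dehmer_entropy(g) == pytest.approx(dehmer_entropy(comp))
        pe_g = partition_entropies(g)
        pe_c = partition_entropies(comp)
        assert pe_g.bonchev_ID == pytest.approx(pe_c.bonchev_ID)
        assert pe_g.bonchev_IDW == pytest.approx(pe_c.bonchev_IDW)
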