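import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gammasfc import (
    EmptyGraphError,
    ParameterError,
    Partition,
    UndefinedDiceError,
    ValidationError,
    chi,
    dice,
    match_density_and_binarize,
    modularity,
    optimize,
    t_fs,
)

from conftest import make_matrix, random_binary_pair
from oracles import modularity_oracle, t_fs_link_oracle


def binary_matrix(edges, n, modality="structural"):
    v = np.zeros((n, n))
    for i, j in edges:
        v[i, j] = v[j, i] = 1.0
    ids = [f"n{i}" for i in range(n)]
    return make_matrix(v, modality, node_ids=ids)


def part(labels):
    return Partition(node_ids=[f"n{i}" for i in range(len(labels))], labels=list(labels))


class TestModularity:
    def test_two_disjoint_cliques(self):
        adj = binary_matrix([(0, 1), (2, 3)], 4)
        assert modularity(adj, part([1, 1, 2, 2])) == pytest.approx(0.5)

    def test_single_module_is_zero(self):
        rng = np.random.default_rng(9)
        adj, _ = random_binary_pair(rng, 8)
        assert modularity(adj, part([1] * 8)) == pytest.approx(0.0, abs=1e-14)

    def test_matches_counting_oracle_on_random_partitions(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            adj, _ = random_binary_pair(rng, n)
            labels = rng.integers(1, 4, size=n).tolist()
            got = modularity(adj, part(labels))
            assert got == pytest.approx(modularity_oracle(adj.values, labels), abs=1e-10)
            assert -0.5 - 1e-12 <= got <= 1.0

    def test_agrees_with_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(13)
        for _ in range(10):
            adj, _ = random_binary_pair(rng, 9)
            labels = rng.integers(1, 4, size=9).tolist()
            g = nx.from_numpy_array(adj.values)
            communities = [
                {i for i in range(9) if labels[i] == c} for c in set(labels)
            ]
            expected = nx.algorithms.community.modularity(g, communities)
            assert modularity(adj, part(labels)) == pytest.approx(expected, abs=1e-10)

    def test_empty_graph_rejected(self):
        adj = binary_matrix([], 4)
        with pytest.raises(EmptyGraphError):
            modularity(adj, part([1, 1, 2, 2]))

    def test_weighted_matrix_rejected(self):
        adj = make_matrix([[0, 0.5], [0.5, 0]], "functional", node_ids=["n0", "n1"])
        with pytest.raises(ValidationError):
            modularity(adj, part([1, 2]))


class TestDice:
    def test_identity(self):
        assert dice({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert dice({"a"}, {"b", "c"}) == 0.0

    def test_half_overlap(self):
        assert dice({"a", "b"}, {"b", "c"}) == 0.5

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedDiceError):
            dice(set(), set())


class TestTfs:
    def make_pair(self, sc_edges, fc_edges, n):
        return match_density_and_binarize(
            binary_matrix(sc_edges, n, "structural"),
            binary_matrix(fc_edges, n, "functional"),
        )

    def test_identical_matrices_give_one(self):
        edges = [(0, 1), (1, 2), (3, 4)]
        pair = self.make_pair(edges, edges, 5)
        for labels in ([1, 1, 1, 2, 2], [1, 1, 2, 2, 2], [1] * 5):
            assert t_fs(pair, part(labels)) == 1.0

    def test_disjoint_intra_links_contribute_zero(self):
        # one module where FC and SC intra-link sets are disjoint
        pair = self.make_pair([(0, 1)], [(1, 2)], 3)
        assert t_fs(pair, part([1, 1, 1])) == 0.0

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            sc, _ = random_binary_pair(rng, n)
            dense = np.triu(0.1 + 0.9 * rng.random((n, n)), 1)
            fc_m = make_matrix(dense + dense.T, "functional", node_ids=sc.node_ids)
            pair = match_density_and_binarize(sc, fc_m)
            labels = rng.integers(1, 4, size=n).tolist()
            got = t_fs(pair, part(labels))
            expected = t_fs_link_oracle(
                pair.fc_bin.values, pair.sc_bin.values, labels
            )
            assert got == pytest.approx(expected, abs=1e-10)

    def test_symmetric_under_modality_swap(self, reference_pair):
        from gammasfc import PopulationPair, cut, build_tree, fuse

        p = cut(build_tree(fuse(reference_pair, 0.5)), 4)
        swapped = PopulationPair(
            sc_bin=make_matrix(
                reference_pair.fc_bin.values, "structural",
                node_ids=reference_pair.node_ids,
            ),
            fc_bin=make_matrix(
                reference_pair.sc_bin.values, "functional",
                node_ids=reference_pair.node_ids,
            ),
            sc_raw_population=reference_pair.sc_raw_population,
            fc_raw_population=reference_pair.fc_raw_population,
            density=reference_pair.density,
        )
        assert t_fs(reference_pair, p) == pytest.approx(t_fs(swapped, p), abs=1e-12)

    def test_node_dice_strategy_on_identical_matrices(self, clique_pair):
        p = Partition(
            node_ids=list(clique_pair.node_ids),
            labels=[i // 5 + 1 for i in range(20)],
        )
        assert t_fs(clique_pair, p, strategy="node-dice") == pytest.approx(1.0)

    def test_unknown_strategy(self, clique_pair):
        p = Partition(node_ids=list(clique_pair.node_ids), labels=[1] * 20)
        with pytest.raises(ParameterError):
            t_fs(clique_pair, p, strategy="bogus")


class TestChi:
    @pytest.mark.parametrize(
        "factors,expected",
        [
            ((0.5, 0.5, 0.5), 0.5),
            ((1.0, 1.0, 1.0), 1.0),
            ((0.4, 0.9, 0.6), 0.6),
        ],
    )
    def test_arithmetic(self, factors, expected):
        assert chi(*factors) == pytest.approx(expected, abs=1e-12)

    def test_negative_factor_is_nan(self):
        assert math.isnan(chi(-0.1, 0.5, 0.5))
        assert math.isnan(chi(0.5, -0.1, 0.5))

    @given(
        base=st.floats(min_value=0.0, max_value=1.0),
        bump=st.floats(min_value=1e-6, max_value=0.5),
        others=st.tuples(
            st.floats(min_value=0.01, max_value=1.0),
            st.floats(min_value=0.01, max_value=1.0),
        ),
    )
    def test_monotone_in_each_factor(self, base, bump, others):
        a, b = others
        assert chi(base + bump, a, b) >= chi(base, a, b)
        assert chi(a, base + bump, b) >= chi(a, base, b)
        assert chi(a, b, base + bump) >= chi(a, b, base)


class TestOptimize:
    def test_planted_cliques_maximize_at_m4_for_every_gamma(self, clique_pair):
        grid = optimize(clique_pair, m_range=range(2, 9))
        # Q of the planted partition: 4 modules, each with 10 intra links of
        # the 40 total and a quarter of the degree
        q_expected = 4 * (10 / 40 - (20 / 80) ** 2)
        for gi in range(len(grid.gammas)):
            best_m = grid.module_counts[int(np.nanargmax(grid.chi[gi]))]
            assert best_m == 4
        g_star, m_star, chi_star = grid.optimum
        assert m_star == 4
        assert chi_star == pytest.approx((q_expected**2) ** (1 / 3), abs=1e-10)

    def test_identical_pair_is_gamma_invariant(self, clique_pair):
        grid = optimize(clique_pair, gammas=[0.0, 0.3, 0.8], m_range=range(2, 7))
        for mi in range(len(grid.module_counts)):
            assert len(set(np.round(grid.chi[:, mi], 12))) == 1
        # ties resolve toward the smallest gamma
        assert grid.optimum[0] == 0.0

    def test_valid_module_counts(self, clique_pair):
        grid = optimize(clique_pair, gammas=[0.0], m_range=range(2, 7), min_module_size=3)
        m4 = grid.module_counts.index(4)
        assert grid.valid_module_counts[0, m4] == 4
        # every cut of 20 nodes into <= 6 parts keeps counts within [0, m]
        assert (grid.valid_module_counts <= np.array(grid.module_counts)).all()

    def test_m_range_validation(self, clique_pair):
        with pytest.raises(ParameterError):
            optimize(clique_pair, m_range=range(1, 5))
        with pytest.raises(ParameterError):
            optimize(clique_pair, m_range=range(2, 50))

    def test_grid_frame_shape(self, clique_pair):
        grid = optimize(clique_pair, gammas=[0.0, 1.0], m_range=range(2, 5))
        frame = grid.to_frame()
        assert len(frame) == 2 * 3
        assert set(frame.columns) == {
            "gamma", "m", "q_f", "q_s", "t_fs", "chi", "n_valid_modules"
        }
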