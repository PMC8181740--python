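import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from counterstream import (
    BinaryNetwork,
    binary_shortest_paths,
    edge_metrics,
    node_reduced_cd,
    optimize_alpha,
    optimize_k,
    relaxed_weighted_paths,
    truncate_paths,
)
from conftest import binary_from_edges, weighted_from_edges
from oracles import (
    eb_cd_bruteforce,
    k_cheapest_paths,
    min_hop_paths,
    random_digraph,
)


class TestBinaryShortestPaths:
    def test_directed_three_cycle(self):
        net = binary_from_edges("abc", [("a", "b"), ("b", "c"), ("c", "a")])
        ps = binary_shortest_paths(net)
        assert ps.pair("a", "b") == [((0, 1), 1.0)]
        assert ps.pair("a", "c") == [((0, 1, 2), 2.0)]

    def test_diamond_retains_both_tied_paths(self, diamond_net):
        ps = binary_shortest_paths(diamond_net)
        got = {p for p, _ in ps.pair("a", "d")}
        assert got == {(0, 1, 3), (0, 2, 3)}

    def test_disconnected_pair_is_empty(self):
        net = binary_from_edges("ab", [])
        ps = binary_shortest_paths(net)
        assert ps.pair("a", "b") == [] and ps.pair("b", "a") == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 6), p=st.floats(0.15, 0.8))
    def test_matches_exhaustive_enumeration(self, seed, n, p):
        """All minimum-hop paths agree with a full path census (<=6 nodes)."""
        A = random_digraph(n, p, np.random.default_rng(seed))
        net = BinaryNetwork([f"n{i}" for i in range(n)], A)
        ps = binary_shortest_paths(net)
        oracle = min_hop_paths(A)
        got = {pair: sorted(p for p, _ in plist) for pair, plist in ps.paths.items()}
        assert got == oracle


class TestRelaxedWeightedPaths:
    def three_node_net(self):
        # direct a->c has cost-base 10; detour a->b->c has two cost-2 hops
        return weighted_from_edges(
            "abc",
            {
                ("a", "c"): (0.5, 0.5, 5.0),   # dist/fln = 10
                ("a", "b"): (0.5, 0.5, 1.0),   # dist/fln = 2
                ("b", "c"): (0.5, 0.5, 1.0),
            },
        )

    def test_alpha_one_prefers_cheap_detour(self):
        ps = relaxed_weighted_paths(self.three_node_net(), alpha=1.0, k=1)
        (path, cost), = ps.pair("a", "c")
        assert path == (0, 1, 2)
        assert cost == pytest.approx(4.0)

    def test_small_alpha_prefers_direct_edge(self):
        ps = relaxed_weighted_paths(self.three_node_net(), alpha=0.1, k=1)
        (path, cost), = ps.pair("a", "c")
        assert path == (0, 2)
        assert cost == pytest.approx(10**0.1)

    def test_alpha_zero_recovers_binary_hop_distances(self, synthetic_connectome):
        net, _ = synthetic_connectome
        ps = relaxed_weighted_paths(net, alpha=0.0, k=1)
        bin_ps = binary_shortest_paths(net.binary())
        for pair, plist in bin_ps.paths.items():
            assert ps.paths[pair][0][1] == pytest.approx(plist[0][1])

    def test_k3_retains_direct_plus_detours(self):
        net = weighted_from_edges(
            "abcd",
            {
                ("a", "d"): (0.5, 0.5, 2.0),
                ("a", "b"): (0.5, 0.5, 1.0),
                ("b", "d"): (0.5, 0.5, 1.0),
                ("a", "c"): (0.5, 0.5, 1.0),
                ("c", "d"): (0.5, 0.5, 1.0),
            },
        )
        ps = relaxed_weighted_paths(net, alpha=1.0, k=3)
        got = {p for p, _ in ps.pair("a", "d")}
        assert got == {(0, 3), (0, 1, 3), (0, 2, 3)}

    def test_negative_alpha_rejected(self, synthetic_connectome):
        with pytest.raises(ValueError):
            relaxed_weighted_paths(synthetic_connectome[0], alpha=-0.5, k=1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 4))
    def test_matches_bruteforce_k_cheapest(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        A = random_digraph(n, 0.5, rng)
        nodes = [f"n{i}" for i in range(n)]
        fln = np.where(A, rng.uniform(0.05, 1.0, (n, n)), np.nan)
        dist = np.where(A, rng.uniform(1.0, 20.0, (n, n)), np.nan)
        from counterstream import WeightedConnectome

        net = WeightedConnectome(nodes, fln, np.where(A, 0.5, np.nan), dist)
        alpha = 0.6
        cost = np.where(A, (dist / fln) ** alpha, np.inf)
        ps = relaxed_weighted_paths(net, alpha, k)
        oracle = k_cheapest_paths(A, cost, k)
        assert set(ps.paths) == set(oracle)
        for pair in oracle:
            assert [p for p, _ in ps.paths[pair]] == [p for p, _ in oracle[pair]]

    def test_truncation_is_prefix_of_larger_k(self, synthetic_connectome):
        net, _ = synthetic_connectome
        big = relaxed_weighted_paths(net, 0.3, 4)
        small = truncate_paths(big, 2)
        direct = relaxed_weighted_paths(net, 0.3, 2)
        assert {p: [q for q, _ in v] for p, v in small.paths.items()} == {
            p: [q for q, _ in v] for p, v in direct.paths.items()
        }


class TestEdgeMetrics:
    def test_path_graph_eb(self):
        net = binary_from_edges("abc", [("a", "b"), ("b", "c")])
        em = edge_metrics(binary_shortest_paths(net), net)
        tab = em.table.set_index(["source", "target"])
        assert tab.loc[("a", "b"), "eb"] == pytest.approx(2.0)
        assert tab.loc[("b", "c"), "eb"] == pytest.approx(2.0)

    def test_diamond_tie_contributes_half(self, diamond_net):
        em = edge_metrics(binary_shortest_paths(diamond_net), diamond_net)
        tab = em.table.set_index(["source", "target"])
        # pair (a,d) splits over two tied paths; pair (a,b) adds 1
        assert tab.loc[("a", "b"), "eb"] == pytest.approx(1.5)

    def test_funnel_cd(self, funnel_net):
        em = edge_metrics(binary_shortest_paths(funnel_net), funnel_net)
        tab = em.table.set_index(["source", "target"])
        assert tab.loc[("c", "d"), "cd"] == pytest.approx(0.5)
        assert tab.loc[("a", "c"), "cd"] == pytest.approx(-1 / 3)

    def test_mirrored_funnel_cd_negated(self):
        net = binary_from_edges("abcd", [("d", "c"), ("c", "a"), ("c", "b")])
        em = edge_metrics(binary_shortest_paths(net), net)
        tab = em.table.set_index(["source", "target"])
        assert tab.loc[("d", "c"), "cd"] == pytest.approx(-0.5)

    def test_isolated_edge_cd_zero(self):
        net = binary_from_edges("ab", [("a", "b")])
        em = edge_metrics(binary_shortest_paths(net), net)
        assert em.table["cd"].tolist() == [0.0]
        assert em.table["in_set_size"].tolist() == [1]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 6))
    def test_eb_cd_match_bruteforce(self, seed, n):
        A = random_digraph(n, 0.45, np.random.default_rng(seed))
        net = BinaryNetwork([f"n{i}" for i in range(n)], A)
        em = edge_metrics(binary_shortest_paths(net), net)
        oracle_paths = min_hop_paths(A)
        eb_o, cd_o = eb_cd_bruteforce(
            oracle_paths, [tuple(e) for e in zip(*np.nonzero(A))]
        )
        for _, row in em.table.iterrows():
            e = (net.nodes.index(row["source"]), net.nodes.index(row["target"]))
            assert row["eb"] == pytest.approx(eb_o[e])
            assert row["cd"] == pytest.approx(cd_o[e])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_cd_reversal_antisymmetry(self, seed):
        """Reversing every edge negates every edge CD."""
        A = random_digraph(5, 0.5, np.random.default_rng(seed))
        nodes = list("vwxyz")
        em_f = edge_metrics(
            binary_shortest_paths(BinaryNetwork(nodes, A)), BinaryNetwork(nodes, A)
        )
        em_r = edge_metrics(
            binary_shortest_paths(BinaryNetwork(nodes, A.T)),
            BinaryNetwork(nodes, A.T),
        )
        fwd = {(r["source"], r["target"]): r["cd"] for _, r in em_f.table.iterrows()}
        rev = {(r["target"], r["source"]): r["cd"] for _, r in em_r.table.iterrows()}
        for e, cd in fwd.items():
            assert rev[e] == pytest.approx(-cd)

    def test_cd_bounds_all_modes(self, synthetic_connectome):
        net, _ = synthetic_connectome
        for em in (
            edge_metrics(binary_shortest_paths(net.binary()), net.binary()),
            edge_metrics(relaxed_weighted_paths(net, 0.3, 3), net),
        ):
            assert em.table["cd"].between(-1, 1).all()
            assert (em.table["eb"] >= 0).all()


class TestNodeReducedCD:
    def test_funnel_example_values(self, funnel_net):
        em = edge_metrics(binary_shortest_paths(funnel_net), funnel_net)
        prof = node_reduced_cd(em, funnel_net).table.set_index("node")
        assert prof.loc["c", "nrcd_in_minus"] == pytest.approx(-2 / 9)
        assert prof.loc["c", "nrcd_out_plus"] == pytest.approx(0.5 / 3)
        assert prof.loc["c", "cd_flow"] == pytest.approx(5 / 6)

    def test_single_edge_all_zero(self):
        net = binary_from_edges("ab", [("a", "b")])
        em = edge_metrics(binary_shortest_paths(net), net)
        prof = node_reduced_cd(em, net).table
        cols = ["nrcd_in_plus", "nrcd_in_minus", "nrcd_out_plus", "nrcd_out_minus",
                "cd_flow"]
        assert np.allclose(prof[cols].to_numpy(), 0.0)

    def test_in_out_bookkeeping_identity(self, synthetic_connectome):
        """Each edge CD appears once on the in side and once on the out side."""
        net = synthetic_connectome[0].binary()
        em = edge_metrics(binary_shortest_paths(net), net)
        prof = node_reduced_cd(em, net).table
        inc = prof["nrcd_in_plus"].sum() + prof["nrcd_in_minus"].sum()
        out = prof["nrcd_out_plus"].sum() + prof["nrcd_out_minus"].sum()
        assert inc == pytest.approx(out)

    def test_quadrant_signs(self, synthetic_connectome):
        net = synthetic_connectome[0].binary()
        em = edge_metrics(binary_shortest_paths(net), net)
        prof = node_reduced_cd(em, net).table
        assert (prof["nrcd_in_plus"] >= 0).all()
        assert (prof["nrcd_out_plus"] >= 0).all()
        assert (prof["nrcd_in_minus"] <= 0).all()
        assert (prof["nrcd_out_minus"] <= 0).all()
        assert prof["cd_flow"].between(-2, 2).all()


class TestOptimisation:
    def test_equal_weights_return_largest_alpha(self):
        net = weighted_from_edges(
            "abcd",
            {(u, v): (0.5, 0.5, 2.0) for u, v in
             [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]},
        )
        chosen, diag = optimize_alpha(net, [0.0, 0.25, 0.5, 0.75, 1.0])
        assert chosen == 1.0
        assert diag["n_zero_eb"].nunique() == 1  # criteria flat in alpha

    def test_hub_path_max_eb_drops_at_small_alpha(self):
        # a super-cheap hub corridor a->b attracts all traffic at alpha = 1
        edges = {}
        nodes = "abcde"
        for u in nodes:
            for v in nodes:
                if u != v:
                    edges[(u, v)] = (0.01, 0.5, 10.0)  # cost-base 1000
        for u in nodes:
            if u != "a":
                edges[(u, "a")] = (1.0, 0.5, 0.1)  # cheap feeder into the hub
            if u != "b":
                edges[("b", u)] = (1.0, 0.5, 0.1)  # cheap fan-out of the hub
        edges[("a", "b")] = (1.0, 0.5, 0.1)
        net = weighted_from_edges(nodes, edges)
        from counterstream import relaxed_weighted_paths as rwp, edge_metrics as em

        max_eb_1 = em(rwp(net, 1.0, 1), net).table["eb"].max()
        max_eb_0 = em(rwp(net, 0.05, 1), net).table["eb"].max()
        assert max_eb_0 < max_eb_1

    def test_unique_path_graph_constant_in_k(self):
        net = weighted_from_edges(
            "abc", {("a", "b"): (0.5, 0.5, 1.0), ("b", "c"): (0.5, 0.5, 1.0)}
        )
        chosen, diag = optimize_k(net, 0.5, [1, 2, 3])
        assert diag["n_zero_cd"].nunique() == 1
        assert diag["eb_kurtosis"].nunique() == 1

    def test_k1_has_maximal_zero_cd_count(self, synthetic_connectome):
        net, _ = synthetic_connectome
        _, diag = optimize_k(net, 0.07, [1, 2, 4, 8])
        assert diag["n_zero_cd"].iloc[0] == diag["n_zero_cd"].max()

    def test_multiplicity_nondecreasing_in_k(self, synthetic_connectome):
        """Pairs with >= 2 retained paths never decrease as k grows."""
        net, _ = synthetic_connectome
        from counterstream import relaxed_weighted_paths as rwp

        full = rwp(net, 0.07, 6)
        counts = []
        for k in (1, 2, 4, 6):
            ps = truncate_paths(full, k)
            counts.append(sum(1 for v in ps.paths.values() if len(v) >= 2))
        assert counts == sorted(counts)

    def test_empty_grid_rejected(self, synthetic_connectome):
        with pytest.raises(ValueError):
            optimize_alpha(synthetic_connectome[0], [])
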