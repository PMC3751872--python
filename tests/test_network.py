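"""Correlation thresholding, RMT/NNSD selection, modules, network comparison."""

import warnings

import networkx as nx
import numpy as np
import pytest

from thermoevo import (
    CorrelationMatrix,
    SimulationConfig,
    build_network,
    compare_networks,
    correlations,
    detect_modules,
    first_neighbors,
    poisson_spacing_test,
    rmt_threshold,
    simulate_expression,
)

from conftest import exhaustive_partitions


def planted_block_cm(n_blocks=2, block=15, noise_sd=0.05, seed=0):
    """Correlation matrix with near-unit within-block r, near-zero between."""
    rng = np.random.default_rng(seed)
    n = n_blocks * block
    m = rng.normal(0.0, noise_sd, size=(n, n))
    m = (m + m.T) / 2
    for b in range(n_blocks):
        s = slice(b * block, (b + 1) * block)
        m[s, s] = rng.uniform(0.985, 0.995, size=(block, block))
        m[s, s] = (m[s, s] + m[s, s].T) / 2
    np.fill_diagonal(m, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return CorrelationMatrix(genes, np.clip(m, -1, 1)), block


class TestCorrelations:
    def test_self_correlation_unity(self, sim_default):
        eset, _ = sim_default
        cm = correlations(eset)
        np.testing.assert_allclose(np.diag(cm.matrix), 1.0)

    def test_negated_gene_anticorrelated(self):
        from thermoevo import ExpressionSet

        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        eset = ExpressionSet(
            ["a", "b"], [("s", r) for r in range(12)], np.vstack([x, -x])
        )
        cm = correlations(eset)
        assert cm.matrix[0, 1] == pytest.approx(-1.0)

    def test_planted_factor_pair_strongly_correlated(self):
        cfg = SimulationConfig(
            n_genes=20, seed=5, de_fraction=0, memory_spec=[],
            module_spec=[(2, 0.98)],
        )
        eset, _ = simulate_expression(cfg)
        cm = correlations(eset)
        assert cm.matrix[0, 1] >= 0.95

    def test_zero_variance_gene_dropped(self):
        from thermoevo import ExpressionSet

        rng = np.random.default_rng(1)
        vals = np.vstack([np.zeros(6), rng.normal(size=(2, 6))])
        eset = ExpressionSet(["flat", "a", "b"],
                             [("s", r) for r in range(6)], vals)
        cm = correlations(eset)
        assert cm.dropped == ["flat"] and cm.genes == ["a", "b"]

    def test_too_few_samples_rejected(self):
        from thermoevo import ExpressionSet

        eset = ExpressionSet(["a"], [("s", 0), ("s", 1)], np.ones((1, 2)))
        with pytest.raises(ValueError):
            correlations(eset)


class TestBuildNetwork:
    def test_threshold_monotonicity_ladder(self, sim_default):
        eset, _ = sim_default
        cm = correlations(eset)
        prev = None
        for theta in (0.5, 0.6, 0.7, 0.8, 0.9):
            edges = set(map(frozenset, build_network(cm, theta).edges))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_planted_clique_complete_at_cutoff(self):
        cm, block = planted_block_cm(n_blocks=1, block=5)
        net = build_network(cm, 0.98)
        assert net.number_of_nodes() == 5
        assert net.number_of_edges() == 10  # complete K5

    def test_unit_threshold_empty_on_noise(self):
        rng = np.random.default_rng(2)
        m = np.clip(rng.normal(0, 0.3, (10, 10)), -0.99, 0.99)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        cm = CorrelationMatrix([f"g{i}" for i in range(10)], m)
        assert build_network(cm, 1.0).number_of_edges() == 0

    def test_edge_sign_annotation(self):
        m = np.array([[1.0, -0.99], [-0.99, 1.0]])
        cm = CorrelationMatrix(["a", "b"], m)
        net = build_network(cm, 0.98)
        assert net.edges["a", "b"]["sign"] == "-"

    def test_bad_threshold_rejected(self, sim_default):
        eset, _ = sim_default
        cm = correlations(eset)
        with pytest.raises(ValueError):
            build_network(cm, 0.0)


class TestRmtThreshold:
    def test_exponential_spacings_accepted(self):
        rng = np.random.default_rng(3)
        accepted = sum(
            poisson_spacing_test(rng.exponential(1.0, size=200)) > 0.05
            for _ in range(100)
        )
        assert accepted >= 90

    def test_wigner_spacings_rejected(self):
        rng = np.random.default_rng(4)
        u = rng.uniform(size=(50, 200))
        rejected = sum(
            poisson_spacing_test(np.sqrt(-4 * np.log(1 - ui) / np.pi)) < 0.05
            for ui in u
        )
        assert rejected >= 45

    def test_planted_blocks_separated_at_selected_threshold(self):
        cm, block = planted_block_cm(n_blocks=2, block=15, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theta = rmt_threshold(cm, grid=np.arange(0.3, 1.0, 0.05))
        net = build_network(cm, theta)
        between = [
            (u, v) for u, v in net.edges
            if int(u[1:]) // block != int(v[1:]) // block
        ]
        assert between == []
        assert net.number_of_edges() > 0  # within-block edges survive

    def test_degenerate_grid_returns_max_with_warning(self):
        cm, _ = planted_block_cm(n_blocks=2, block=10)
        with pytest.warns(UserWarning):
            assert rmt_threshold(cm, grid=[1.0]) == 1.0

    def test_small_matrix_rejected(self):
        cm = CorrelationMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError):
            rmt_threshold(cm)


class TestDetectModules:
    def test_two_disjoint_cliques_match_exhaustive(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part = detect_modules(g)
        assert sorted(part.sizes.values()) == [5, 5]
        best_q = max(
            nx.community.modularity(g, [set(b) for b in p])
            for p in exhaustive_partitions(list(g.nodes))
        )
        assert part.modularity == pytest.approx(best_q)

    def test_single_edge_one_module(self):
        g = nx.Graph([("a", "b")])
        part = detect_modules(g)
        assert part.assignments["a"] == part.assignments["b"]

    def test_complete_graph_one_module(self):
        part = detect_modules(nx.complete_graph(6))
        assert len(part.sizes) == 1

    def test_small_modules_reported_not_dropped(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(3))
        part = detect_modules(g, min_size=5)
        assert len(part.sizes) == 2 and part.small_modules == [2]
        assert len(part.assignments) == 9

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(nx.Graph())

    def test_planted_module_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(
            n_genes=60, seed=8, de_fraction=0, memory_spec=[],
            module_spec=[(10, 0.95)] * 4,
        )
        eset, truth = simulate_expression(cfg)
        cm = correlations(eset)
        net = build_network(cm, 0.8)
        part = detect_modules(net)
        nodes = [n for n in net.nodes if n in truth.module_membership]
        planted = [truth.module_membership[n] for n in nodes]
        found = [part.assignments[n] for n in nodes]
        assert adjusted_rand_score(planted, found) >= 0.9


class TestCompareNetworks:
    def test_printed_node_accounting(self):
        a = nx.empty_graph()
        b = nx.empty_graph()
        shared = [f"s{i}" for i in range(186)]
        a.add_edges_from((n, "hubA") for n in shared + [f"a{i}" for i in range(29)])
        b.add_edges_from((n, "hubB") for n in shared + [f"b{i}" for i in range(96)])
        # hubs count as nodes: 186 shared + 29 + hubA = 216; 186 + 96 + hubB = 283
        assert a.number_of_nodes() == 216 and b.number_of_nodes() == 283
        comp = compare_networks(a, b)
        assert len(comp.shared) == 186
        assert len(comp.a_specific) == 30 and len(comp.b_specific) == 97
        assert comp.shrinkage_percent == pytest.approx(23.7, abs=0.05)

    def test_identical_networks(self):
        g = nx.complete_graph(4)
        comp = compare_networks(g, g)
        assert comp.shared == set(g.nodes)
        assert not comp.a_specific and not comp.b_specific
        assert comp.shrinkage_percent == 0.0

    def test_disjoint_networks(self):
        a = nx.complete_graph(["a1", "a2"])
        b = nx.complete_graph(["b1", "b2"])
        comp = compare_networks(a, b)
        assert comp.shared == set()

    def test_accounting_identities(self, sim_default):
        eset, _ = sim_default
        cm = correlations(eset)
        a = build_network(cm, 0.7)
        b = build_network(cm, 0.6)
        comp = compare_networks(a, b)
        assert len(comp.shared) + len(comp.a_specific) == a.number_of_nodes()
        assert len(comp.shared) + len(comp.b_specific) == b.number_of_nodes()

    def test_hub_table_sorted_by_degree(self):
        g = nx.star_graph(5)
        comp = compare_networks(g, g, k=3)
        assert comp.hubs_a[0] == (0, 5)


class TestFirstNeighbors:
    def test_isolated_seed_alone(self):
        g = nx.Graph()
        g.add_node("seed")
        g.add_edge("x", "y")
        sub = first_neighbors(g, ["seed"])
        assert set(sub.nodes) == {"seed"}

    def test_seed_in_clique_returns_clique(self):
        g = nx.complete_graph(5)
        sub = first_neighbors(g, [0])
        assert set(sub.nodes) == set(g.nodes)
        assert sub.number_of_edges() == g.number_of_edges()

    def test_star_centre_returns_star(self):
        g = nx.star_graph(6)
        sub = first_neighbors(g, [0])
        assert set(sub.nodes) == set(g.nodes)

    def test_all_seeds_absent_rejected(self):
        with pytest.raises(ValueError):
            first_neighbors(nx.complete_graph(3), ["nope"])

    def test_missing_seed_warned_not_fatal(self):
        g = nx.complete_graph(3)
        with pytest.warns(UserWarning):
            sub = first_neighbors(g, [0, "nope"])
        assert 0 in sub
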