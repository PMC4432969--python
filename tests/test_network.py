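"""BUM fitting, node scoring, subnetwork search and merging."""

import math

import networkx as nx
import numpy as np
import pytest

from emtkit import (BumFit, InputError, NumericalError, Subnetwork,
                    exhaustive_max_subnetwork, find_max_subnetwork, fit_bum,
                    merge_networks, score_nodes, simulate_bum_pvalues)


class TestFitBum:
    def test_uniform_null_limit(self):
        rng = np.random.default_rng(0)
        fit = fit_bum(rng.random(10_000))
        assert fit.pi_upper == pytest.approx(1.0, abs=0.05)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        p = simulate_bum_pvalues(10_000, lam=0.6, a=0.3, rng=rng)
        fit = fit_bum(p)
        assert fit.lam == pytest.approx(0.6, abs=0.1)
        assert fit.a == pytest.approx(0.3, abs=0.1)

    def test_ml_dominates_truth(self):
        rng = np.random.default_rng(2)
        p = simulate_bum_pvalues(5000, lam=0.7, a=0.4, rng=rng)
        fit = fit_bum(p)
        ll_truth = float(np.sum(np.log(0.7 + 0.3 * 0.4 * p ** (0.4 - 1.0))))
        assert fit.log_likelihood >= ll_truth - 1e-6

    def test_degenerate_input_rejected(self):
        with pytest.raises(NumericalError):
            fit_bum([0.5] * 200)


class TestScoreNodes:
    def fit(self, lam=0.8, a=0.5):
        return BumFit(lam=lam, a=a, log_likelihood=0.0, n=1000)

    def test_score_zero_at_tau(self):
        scores = score_nodes(self.fit(), 0.01, {"G": 0.5})
        tau = scores.tau
        at_tau = score_nodes(self.fit(), 0.01, {"G": tau})
        assert at_tau["G"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_score(self):
        # s = (a-1)*(ln p - ln tau) with a=0.5, tau=0.01, p=1e-4 -> 2.3026
        s = (0.5 - 1.0) * (math.log(1e-4) - math.log(1e-2))
        assert s == pytest.approx(2.3026, abs=1e-4)
        scores = score_nodes(self.fit(a=0.5), 0.01, {"G": 1e-4})
        expected = (0.5 - 1.0) * (math.log(1e-4) - math.log(scores.tau))
        assert scores["G"] == pytest.approx(expected)

    def test_monotone_decreasing_in_p(self):
        rng = np.random.default_rng(3)
        p = dict(enumerate(np.sort(rng.random(50))))
        scores = score_nodes(self.fit(), 0.05, p)
        vals = [scores[k] for k in sorted(p)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_unachievable_fdr_rejected(self):
        # nearly-uniform mixture: estimated FDR ~ 1 everywhere
        with pytest.raises(NumericalError):
            score_nodes(self.fit(lam=0.999, a=0.999), 1e-6, {"G": 0.5})


def star(scores):
    graph = nx.Graph()
    nodes = sorted(scores)
    graph.add_nodes_from(nodes)
    return graph


class TestExhaustive:
    def path_graph(self, scores):
        graph = nx.path_graph(["A", "B", "C"])
        return graph, scores

    def test_hand_enumerated_path(self):
        graph, scores = self.path_graph({"A": 2.0, "B": -1.0, "C": 2.0})
        sub = exhaustive_max_subnetwork(graph, scores)
        assert sub.nodes == ("A", "B", "C")
        assert sub.total_score == pytest.approx(3.0)

    def test_tie_breaks_lexicographic(self):
        graph, scores = self.path_graph({"A": 2.0, "B": -5.0, "C": 2.0})
        sub = exhaustive_max_subnetwork(graph, scores)
        assert sub.nodes == ("A",)
        assert sub.total_score == pytest.approx(2.0)

    def test_single_node(self):
        graph = nx.Graph()
        graph.add_node("X")
        sub = exhaustive_max_subnetwork(graph, {"X": -3.0})
        assert sub.nodes == ("X",)

    def test_size_limit(self):
        graph = nx.path_graph(20)
        with pytest.raises(InputError):
            exhaustive_max_subnetwork(graph, {v: 1.0 for v in graph})


class TestGreedy:
    def test_all_negative_returns_best_single(self):
        graph = nx.path_graph(["A", "B", "C"])
        sub = find_max_subnetwork(graph, {"A": -3.0, "B": -0.5, "C": -2.0})
        assert sub.nodes == ("B",)

    def test_all_positive_returns_everything(self):
        graph = nx.erdos_renyi_graph(15, 0.3, seed=1)
        graph.add_edges_from((i, i + 1) for i in range(14))  # ensure connected
        scores = {v: 0.5 + v * 0.01 for v in graph}
        sub = find_max_subnetwork(graph, scores)
        assert set(sub.nodes) == set(graph.nodes)

    def test_score_is_exact_sum(self):
        rng = np.random.default_rng(5)
        graph = nx.random_labeled_tree(12, seed=2)
        scores = {v: float(rng.normal()) for v in graph}
        sub = find_max_subnetwork(graph, scores)
        assert sub.total_score == pytest.approx(
            sum(scores[v] for v in sub.nodes))

    def test_near_optimal_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            graph = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            graph.add_edges_from((i, i + 1) for i in range(n - 1))
            scores = {v: float(rng.normal(0.0, 2.0)) for v in graph}
            exact = exhaustive_max_subnetwork(graph, scores)
            greedy = find_max_subnetwork(graph, scores)
            bound = 0.95 * exact.total_score if exact.total_score > 0 \
                else exact.total_score
            assert greedy.total_score >= bound - 1e-9
            best_single = max(scores.values())
            assert greedy.total_score >= best_single - 1e-9

    def test_equals_optimum_on_trees(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(3, 12))
            graph = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
            scores = {v: float(rng.normal(0.0, 2.0)) for v in graph}
            exact = exhaustive_max_subnetwork(graph, scores)
            greedy = find_max_subnetwork(graph, scores)
            assert greedy.total_score == pytest.approx(exact.total_score)


class TestPlantedRecovery:
    def test_module_recovered_from_simulation(self, small_config,
                                              expression_sim, ppi_sim):
        pvals = expression_sim.tables[small_config.module_comparison].pvalues()
        fit = fit_bum(list(pvals.values()))
        scores = score_nodes(fit, 0.001,
                             {g: p for g, p in pvals.items()
                              if g in ppi_sim.graph})
        sub = find_max_subnetwork(ppi_sim.graph, scores)
        module = ppi_sim.planted_module
        overlap = len(set(sub.nodes) & module)
        assert overlap / len(module) >= 0.6
        assert overlap / len(set(sub.nodes) | module) >= 0.4


class TestMerge:
    def test_idempotent_on_identical_inputs(self):
        parent = nx.cycle_graph(["A", "B", "C", "D"])
        sub = Subnetwork(nodes=("A", "B"), total_score=1.0)
        merged = merge_networks(sub, sub, parent)
        assert set(merged.nodes) == {"A", "B"}
        assert all(v == "both" for v in merged.origin.values())

    def test_disjoint_union(self):
        parent = nx.Graph([("A", "B"), ("C", "D")])
        merged = merge_networks(Subnetwork(("A", "B"), 1.0),
                                Subnetwork(("C", "D"), 1.0), parent,
                                label_a="EGF", label_b="HPX")
        assert merged.origin == {"A": "EGF", "B": "EGF",
                                 "C": "HPX", "D": "HPX"}
        assert nx.number_connected_components(merged.graph) == 2

    def test_degree_matches_adjacency_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(20):
            parent = nx.gnp_random_graph(20, 0.2,
                                         seed=int(rng.integers(2**31)))
            nodes = list(parent)
            a = rng.choice(nodes, 8, replace=False)
            b = rng.choice(nodes, 8, replace=False)
            merged = merge_networks(Subnetwork(tuple(sorted(map(int, a))), 0.0),
                                    Subnetwork(tuple(sorted(map(int, b))), 0.0),
                                    parent)
            union = set(map(int, a)) | set(map(int, b))
            for v in merged.nodes:
                oracle = sum(1 for u in parent.neighbors(v) if u in union)
                assert merged.degree[v] == oracle

    def test_node_outside_parent_rejected(self):
        parent = nx.path_graph(["A", "B"])
        with pytest.raises(InputError):
            merge_networks(Subnetwork(("A",), 0.0),
                           Subnetwork(("Z",), 0.0), parent)
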