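import networkx as nx
import numpy as np
import pytest

from conftest import random_instance
from prizenet import pcsf
from prizenet.errors import SizeError
from prizenet.prize_network import PCSFInstance


class TestObjectiveValue:
    def test_empty_forest_pays_all_prizes(self, t1_instance):
        assert pcsf.objective_value(t1_instance, []) == pytest.approx(10.0)

    def test_single_tree(self, t1_instance):
        trees = [({"A", "B"}, {("A", "B")})]
        assert pcsf.objective_value(t1_instance, trees) == pytest.approx(3.0)

    def test_two_singletons(self, t1_graph):
        inst = PCSFInstance(
            graph=t1_graph, prizes={"A": 5.0, "B": 5.0}, beta=1.0, omega=0.5
        )
        trees = [({"A"}, set()), ({"B"}, set())]
        assert pcsf.objective_value(inst, trees) == pytest.approx(1.0)

    def test_cycle_rejected(self, t1_instance):
        trees = [({"A", "B", "C"}, {("A", "B"), ("B", "C"), ("A", "C")})]
        with pytest.raises(ValueError):
            pcsf.objective_value(t1_instance, trees)

    def test_foreign_edge_rejected(self, t1_instance):
        trees = [({"A", "Z"}, {("A", "Z")})]
        with pytest.raises(ValueError):
            pcsf.objective_value(t1_instance, trees)


class TestSolveExact:
    def test_t1_high_omega_single_tree(self, t1_instance):
        sol = pcsf.solve_exact(t1_instance)
        assert sol.objective == pytest.approx(3.0)
        assert [sorted(t[0]) for t in sol.trees] == [["A", "B"]]
        assert sol.kappa == 1

    def test_t1_low_omega_two_singletons(self, t1_graph):
        inst = PCSFInstance(
            graph=t1_graph, prizes={"A": 5.0, "B": 5.0}, beta=1.0, omega=0.5
        )
        sol = pcsf.solve_exact(inst)
        assert sol.objective == pytest.approx(1.0)
        assert sol.kappa == 2
        assert sol.nodes == {"A", "B"}

    def test_zero_prizes_empty_forest(self, t1_graph):
        inst = PCSFInstance(graph=t1_graph, prizes={}, beta=1.0, omega=1.0)
        sol = pcsf.solve_exact(inst)
        assert sol.trees == () and sol.objective == 0.0

    def test_guard_size(self):
        g = nx.path_graph(20)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(20)})
        nx.set_edge_attributes(g, 1.0, "cost")
        inst = PCSFInstance(graph=g, prizes={"N0": 1.0}, beta=1.0, omega=1.0)
        with pytest.raises(SizeError, match="solve_heuristic"):
            pcsf.solve_exact(inst)


class TestSolveHeuristic:
    def test_matches_exact_on_t1(self, t1_graph, t1_instance):
        assert pcsf.solve_heuristic(t1_instance).objective == pytest.approx(3.0)
        low = PCSFInstance(
            graph=t1_graph, prizes={"A": 5.0, "B": 5.0}, beta=1.0, omega=0.5
        )
        assert pcsf.solve_heuristic(low).objective == pytest.approx(1.0)

    def test_zero_prizes_empty(self, t1_graph):
        inst = PCSFInstance(graph=t1_graph, prizes={}, beta=1.0, omega=1.0)
        assert pcsf.solve_heuristic(inst).trees == ()

    def test_disconnected_components_never_bridged(self):
        g = nx.Graph()
        g.add_edge("A1", "A2", cost=0.1)
        g.add_edge("B1", "B2", cost=0.1)
        inst = PCSFInstance(
            graph=g,
            prizes={"A1": 3.0, "A2": 3.0, "B1": 3.0, "B2": 3.0},
            beta=1.0,
            omega=1.0,
        )
        sol = pcsf.solve_heuristic(inst)
        assert sol.kappa >= 2
        for u, v in sol.edges:
            assert u[0] == v[0]  # edges stay within a component

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        inst = random_instance(rng)
        a = pcsf.solve_heuristic(inst)
        b = pcsf.solve_heuristic(inst)
        assert a == b

    def test_steiner_node_labeling(self):
        # prize nodes at the ends force the middle node in as a Steiner node
        g = nx.Graph()
        g.add_edge("A", "M", cost=0.2)
        g.add_edge("M", "B", cost=0.2)
        inst = PCSFInstance(
            graph=g, prizes={"A": 5.0, "B": 5.0}, beta=1.0, omega=2.0
        )
        sol = pcsf.solve_heuristic(inst)
        assert sol.nodes == {"A", "B", "M"}
        assert sol.node_roles["M"] == "steiner"


class TestPrune:
    def test_zero_prize_leaf_removed(self, t1_instance):
        forest = pcsf.ForestSolution(
            trees=(
                (
                    frozenset({"A", "B", "C"}),
                    frozenset({("A", "B"), ("B", "C")}),
                ),
            ),
            kappa=1,
            objective=13.0,
            node_roles={},
        )
        pruned = pcsf.prune(t1_instance, forest)
        assert pruned.nodes == {"A", "B"}
        assert pruned.objective == pytest.approx(3.0)

    def test_fixed_point_on_optimal_tree(self, t1_instance):
        forest = pcsf.ForestSolution(
            trees=((frozenset({"A", "B"}), frozenset({("A", "B")})),),
            kappa=1,
            objective=3.0,
            node_roles={},
        )
        assert pcsf.prune(t1_instance, forest).trees == forest.trees

    def test_zero_prize_singleton_removed(self, t1_instance):
        forest = pcsf.ForestSolution(
            trees=((frozenset({"C"}), frozenset()),),
            kappa=1,
            objective=12.0,
            node_roles={},
        )
        assert pcsf.prune(t1_instance, forest).trees == ()

    def test_idempotent_on_random_solutions(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            inst = random_instance(rng)
            sol = pcsf.solve_heuristic(inst)
            once = pcsf.prune(inst, sol)
            twice = pcsf.prune(inst, once)
            assert once == twice


class TestOracleProperties:
    def test_heuristic_bounded_by_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            inst = random_instance(rng)
            exact = pcsf.solve_exact(inst)
            heur = pcsf.solve_heuristic(inst)
            assert heur.objective >= exact.objective - 1e-9
            assert heur.objective <= 2 * exact.objective + inst.omega + 1e-9

    def test_objective_recomputable(self):
        rng = np.random.default_rng(321)
        for _ in range(20):
            inst = random_instance(rng)
            sol = pcsf.solve_heuristic(inst)
            assert sol.objective == pytest.approx(
                pcsf.objective_value(inst, sol.trees), abs=1e-9
            )

    def test_kappa_non_increasing_in_omega(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            base = random_instance(rng, max_nodes=8)
            kappas = []
            for omega in (0.25, 0.5, 1.0, 2.0, 4.0):
                inst = PCSFInstance(
                    graph=base.graph,
                    prizes=base.prizes,
                    beta=1.0,
                    omega=omega,
                )
                kappas.append(pcsf.solve_exact(inst).kappa)
            assert all(a >= b for a, b in zip(kappas, kappas[1:]))
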