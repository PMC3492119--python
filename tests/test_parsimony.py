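"""Dynamic programs: examples, variants, and oracle cross-checks."""

import numpy as np
import pytest

import parsinet as pn
from parsinet.oracle import BoundedSearchFailure, brute_force_min_flips

from conftest import make_random_forest, make_random_graph


def graph(nodes, edges, **kw):
    return pn.InteractionGraph.from_edges(nodes, edges, **kw)


def no_cheaper_solution(F, G, cost, require_valid):
    """True iff exhaustive search finds nothing strictly cheaper."""
    if cost < 1:
        return True
    try:
        brute_force_min_flips(F, G, max_flips=int(round(cost)) - 1,
                              require_valid=require_valid)
    except BoundedSearchFailure:
        return True
    return False


class TestUndirected:
    def test_single_edge_on_a_cherry_costs_one(self, cherry_forest):
        G = graph(["a", "b", "c"], [("a", "b")])
        cost, tables = pn.min_flip_cost(cherry_forest, G)
        assert cost == 1
        flips = pn.backtrack(tables)
        assert len(flips) == 1
        assert pn.constructs(pn.NetworkHistory(cherry_forest, flips)) == G

    def test_empty_graph_costs_nothing(self, cherry_forest):
        G = graph(["a", "b", "c"], [])
        cost, tables = pn.min_flip_cost(cherry_forest, G)
        assert cost == 0
        assert pn.backtrack(tables) == []

    def test_shared_neighbour_is_cheapest_at_the_duplication_node(
            self, cherry_forest):
        G = graph(["a", "b", "c"], [("a", "c"), ("b", "c")])
        cost, tables = pn.min_flip_cost(cherry_forest, G)
        assert cost == 1
        flips = pn.backtrack(tables)
        assert {f.pair() for f in flips} == {("c", "r")}

    def test_graph_node_not_a_present_leaf_is_an_error(self, cherry_forest):
        G = graph(["a", "zz"], [("a", "zz")])
        with pytest.raises(pn.InputError):
            pn.min_flip_cost(cherry_forest, G)

    def test_cost_never_exceeds_one_event_per_edge(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            F = make_random_forest(rng)
            G = make_random_graph(F, rng)
            cost, _ = pn.min_flip_cost(F, G)
            assert cost <= G.n_edges()

    def test_round_trip_and_lower_bound_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            F = make_random_forest(rng)
            G = make_random_graph(F, rng, p_edge=0.25)
            cost, tables = pn.min_flip_cost(F, G)
            flips = pn.backtrack(tables)
            assert pn.constructs(pn.NetworkHistory(F, flips)) == G
            assert len(flips) == cost
            if cost <= 5:  # keep the exhaustive certificate tractable
                assert no_cheaper_solution(F, G, cost, require_valid=False)

    def test_cost_scaling_is_linear(self, cherry_forest):
        G = graph(["a", "b", "c"], [("a", "c"), ("b", "c"), ("a", "b")])
        base, t0 = pn.min_flip_cost(cherry_forest, G)
        lam = 3.5
        scaled, t1 = pn.min_flip_cost(
            cherry_forest, G, pn.CostModel(c_add=lam, c_loss=lam))
        assert scaled == pytest.approx(lam * base)
        assert ({f.pair() for f in pn.backtrack(t0)}
                == {f.pair() for f in pn.backtrack(t1)})

    def test_forbidding_pairs_never_helps(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            F = make_random_forest(rng)
            G = make_random_graph(F, rng)
            cost0, _ = pn.min_flip_cost(F, G)
            internal = [n.id for n in F.nodes.values() if not n.is_leaf]
            if not internal:
                continue
            forb = {frozenset((internal[0], v)) for v in F.nodes
                    if v != internal[0]}
            cost1, _ = pn.min_flip_cost(F, G, forbidden=forb)
            assert cost1 >= cost0


class TestSelfLoops:
    def test_single_present_leaf_with_homodimer(self):
        F = pn.DuplicationForest()
        F.add_singleton("a")
        G = graph(["a"], [("a", "a")], selfloops=True)
        cost, _ = pn.min_flip_cost_selfloops(F, G)
        assert cost == 1

    def test_self_flip_at_root_explains_clique_with_homodimers(
            self, cherry_forest):
        G = graph(["a", "b", "c"],
                  [("a", "b"), ("a", "a"), ("b", "b")], selfloops=True)
        cost, tables = pn.min_flip_cost_selfloops(cherry_forest, G)
        assert cost == 1
        flips = pn.backtrack(tables)
        assert flips == [pn.FlipEdge("r", "r")]
        h = pn.NetworkHistory(cherry_forest, flips, selfloops=True)
        assert pn.constructs(h) == G

    def test_plain_edge_does_not_tempt_a_self_flip(self, cherry_forest):
        G = graph(["a", "b", "c"], [("a", "b")], selfloops=True)
        cost, tables = pn.min_flip_cost_selfloops(cherry_forest, G)
        assert cost == 1
        h = pn.NetworkHistory(cherry_forest, pn.backtrack(tables),
                              selfloops=True)
        assert pn.constructs(h) == G


class TestDirected:
    def test_shared_target_flip_at_duplication_node(self, cherry_forest):
        G = graph(["a", "b", "c"], [("a", "c"), ("b", "c")], directed=True)
        cost, tables = pn.min_flip_cost_directed(cherry_forest, G)
        assert cost == 1
        flips = pn.backtrack(tables)
        assert len(flips) == 1 and flips[0].pair() == ("c", "r")
        h = pn.NetworkHistory(cherry_forest, flips, directed=True)
        assert pn.constructs(h) == G

    def test_single_arc_costs_one(self, cherry_forest):
        G = graph(["a", "b", "c"], [("a", "c")], directed=True)
        cost, _ = pn.min_flip_cost_directed(cherry_forest, G)
        assert cost == 1

    def test_mirror_graph_has_equal_cost(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            F = make_random_forest(rng)
            G = make_random_graph(F, rng, directed=True, p_edge=0.25)
            M = pn.InteractionGraph.from_edges(
                G.nodes, [(v, u) for u, v in G.g.edges], directed=True)
            c1, _ = pn.min_flip_cost_directed(F, G)
            c2, _ = pn.min_flip_cost_directed(F, M)
            assert c1 == c2

    def test_round_trip_and_lower_bound_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            F = make_random_forest(rng)
            G = make_random_graph(F, rng, directed=True, p_edge=0.2)
            cost, tables = pn.min_flip_cost_directed(F, G)
            flips = pn.backtrack(tables)
            h = pn.NetworkHistory(F, flips, directed=True)
            assert pn.constructs(h) == G
            assert sum(f.n_events for f in flips) == cost
            if cost <= 4:  # keep the exhaustive certificate tractable
                assert no_cheaper_solution(F, G, cost, require_valid=False)


class TestBranchPenalty:
    @staticmethod
    def timed_node(nid, tc, td):
        return pn.TreeNode(id=nid, t_c=tc, t_d=td)

    def test_overlapping_intervals_cost_nothing(self):
        assert pn.branch_penalty(self.timed_node("u", 0, 5),
                                 self.timed_node("v", 3, 8)) == 0

    def test_gap_between_intervals(self):
        assert pn.branch_penalty(self.timed_node("u", 0, 2),
                                 self.timed_node("v", 5, 9)) == 3
        assert pn.branch_penalty(self.timed_node("v", 5, 9),
                                 self.timed_node("u", 0, 2)) == 3

    def test_missing_times_raise_config_error(self):
        with pytest.raises(pn.ConfigError):
            pn.branch_penalty(pn.TreeNode(id="u"), self.timed_node("v", 0, 1))

    @staticmethod
    def _timed_forest():
        """Two cherries whose internal nodes lived in disjoint epochs."""
        F = pn.DuplicationForest()
        F.add_singleton("r")
        F.split_leaf("r", "a", "b")
        F.add_singleton("s")
        F.split_leaf("s", "c", "d")
        times = {"r": (0, 1), "s": (10, 11),
                 "a": (1, None), "b": (1, None),
                 "c": (11, None), "d": (11, None)}
        for nid, (tc, td) in times.items():
            F[nid].t_c, F[nid].t_d = tc, td
        return F

    def test_zero_alpha_matches_unpenalized_recurrence(self):
        F = self._timed_forest()
        G = graph(["a", "b", "c", "d"], [("a", "c"), ("b", "c")])
        c0, _ = pn.min_flip_cost(F, G)
        c1, _ = pn.min_flip_cost(F, G, pn.CostModel(alpha=0.0))
        assert c0 == c1 == 1

    def test_finite_alpha_penalizes_non_overlapping_flips(self):
        F = self._timed_forest()
        G = graph(["a", "b", "c", "d"], [("a", "c"), ("b", "c")])
        # flip {r, c}: r existed in [0,1), c from 11 on -> delta = 10
        cost, _ = pn.min_flip_cost(F, G, pn.CostModel(alpha=0.05))
        assert cost == pytest.approx(1 + 0.05 * 10)
        # large alpha makes two leaf-level flips cheaper than the penalty
        cost, tables = pn.min_flip_cost(F, G, pn.CostModel(alpha=0.5))
        assert cost == 2
        assert all(f.pair() in {("a", "c"), ("b", "c")}
                   for f in pn.backtrack(tables))

    def test_infinite_alpha_is_a_hard_constraint(self):
        F = self._timed_forest()
        G = graph(["a", "b", "c", "d"], [("a", "c"), ("b", "c")])
        cost, tables = pn.min_flip_cost(F, G, pn.CostModel(alpha=float("inf")))
        assert cost == 2  # the {r,c} shortcut is excluded entirely
        flips = pn.backtrack(tables)
        assert {f.pair() for f in flips} == {("a", "c"), ("b", "c")}
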