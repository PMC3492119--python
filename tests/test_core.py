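"""The parity rule, blocking-loop detection and time assignment."""

import numpy as np
import pytest

import parsinet as pn
from parsinet.core import check_time_conditions

from conftest import make_random_history


def hist(F, flips, **kw):
    return pn.NetworkHistory(F, flips, **kw)


class TestConstructs:
    def test_empty_flip_set_gives_empty_graph(self, cherry_forest):
        G = pn.constructs(hist(cherry_forest, []))
        assert G.nodes == {"a", "b", "c"}
        assert G.edge_set() == set()

    def test_single_leaf_level_flip(self, cherry_forest):
        G = pn.constructs(hist(cherry_forest, [pn.FlipEdge("a", "c")]))
        assert G.edge_set() == {frozenset(("a", "c"))}

    def test_parity_cancellation_above_a_leaf(self, cherry_forest):
        # {r,c} toggles (a,c) and (b,c); {a,c} toggles (a,c) back off
        G = pn.constructs(hist(cherry_forest,
                               [pn.FlipEdge("r", "c"), pn.FlipEdge("a", "c")]))
        assert G.edge_set() == {frozenset(("b", "c"))}

    def test_flip_order_is_irrelevant(self, cherry_forest):
        flips = [pn.FlipEdge("r", "c"), pn.FlipEdge("a", "c"),
                 pn.FlipEdge("a", "b")]
        G1 = pn.constructs(hist(cherry_forest, flips))
        G2 = pn.constructs(hist(cherry_forest, flips[::-1]))
        assert G1 == G2

    def test_absent_leaves_are_excluded(self, cherry_forest):
        cherry_forest.set_absent("b")
        G = pn.constructs(hist(cherry_forest, [pn.FlipEdge("r", "c")]))
        assert G.nodes == {"a", "c"}
        assert G.edge_set() == {frozenset(("a", "c"))}

    def test_unknown_endpoint_is_an_input_error(self, cherry_forest):
        with pytest.raises(pn.InputError):
            pn.constructs(hist(cherry_forest, [pn.FlipEdge("a", "zz")]))

    def test_self_flip_requires_selfloop_variant(self, cherry_forest):
        h = hist(cherry_forest, [pn.FlipEdge("r", "r")])
        with pytest.raises(pn.ModelError):
            pn.constructs(h)
        h = hist(cherry_forest, [pn.FlipEdge("r", "r")], selfloops=True)
        G = pn.constructs(h)
        assert G.edge_set() == {frozenset(("a", "b")), frozenset(("a",)),
                                frozenset(("b",))}

    def test_directed_flip_orientation(self, cherry_forest):
        h = hist(cherry_forest, [pn.FlipEdge("r", "c", pn.FORWARD)],
                 directed=True)
        assert pn.constructs(h).edge_set() == {("a", "c"), ("b", "c")}
        h = hist(cherry_forest, [pn.FlipEdge("r", "c", pn.BOTH)],
                 directed=True)
        assert pn.constructs(h).edge_set() == {("a", "c"), ("b", "c"),
                                               ("c", "a"), ("c", "b")}

    def test_leaf_flips_reconstruct_any_graph_and_are_valid(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            h = make_random_history(rng, max_flips=0)
            F = h.forest
            pres = sorted(F.present_leaves())
            rng2 = np.random.default_rng(int(rng.integers(2 ** 31)))
            flips = [pn.FlipEdge(u, v) for i, u in enumerate(pres)
                     for v in pres[i + 1:] if rng2.random() < 0.4]
            h = hist(F, flips)
            G = pn.constructs(h)
            assert G.edge_set() == {frozenset((f.a, f.b)) for f in flips}
            assert pn.is_valid(h)


class TestBlockingLoops:
    def test_ancestor_descendant_flip_is_a_one_loop(self, cherry_forest):
        loop = pn.find_blocking_loop(hist(cherry_forest,
                                          [pn.FlipEdge("r", "a")]))
        assert loop is not None and len(loop) == 1

    def test_crossed_pair_is_a_two_loop(self):
        F = pn.DuplicationForest()
        F.add_singleton("r")
        F.split_leaf("r", "a", "b")
        F.add_singleton("s")
        F.split_leaf("s", "c", "d")
        # u1=s ancestor of v0=c, u0=r ancestor of v1=a
        flips = [pn.FlipEdge("r", "c"), pn.FlipEdge("s", "a")]
        loop = pn.find_blocking_loop(hist(F, flips))
        assert loop is not None and len(loop) == 2

    def test_leaf_only_flips_never_block(self, cherry_forest):
        flips = [pn.FlipEdge("a", "c"), pn.FlipEdge("b", "c"),
                 pn.FlipEdge("a", "b")]
        assert pn.find_blocking_loop(hist(cherry_forest, flips)) is None

    def test_three_loop_across_trees(self):
        F = pn.DuplicationForest()
        for t in range(3):
            F.add_singleton(f"r{t}")
            F.split_leaf(f"r{t}", f"a{t}", f"b{t}")
        flips = [pn.FlipEdge("r0", "a1"), pn.FlipEdge("r1", "a2"),
                 pn.FlipEdge("r2", "a0")]
        loop = pn.find_blocking_loop(hist(F, flips))
        assert loop is not None and len(loop) == 3


class TestAssignTimes:
    def test_leaf_flips_admit_times_satisfying_conditions(self, cherry_forest):
        h = hist(cherry_forest, [pn.FlipEdge("a", "c"), pn.FlipEdge("a", "b")])
        ta = pn.assign_times(h)
        assert ta.ok
        assert all(ta.t_c[r] == 0 for r in cherry_forest.roots)
        assert check_time_conditions(h, ta)

    def test_one_loop_stalls(self, cherry_forest):
        ta = pn.assign_times(hist(cherry_forest, [pn.FlipEdge("r", "a")]))
        assert not ta.ok
        assert "r" in ta.stalled

    def test_equivalence_with_loop_detection(self):
        """Existence of a consistent timing <=> absence of blocking loops,
        on a mixed population of random histories."""
        rng = np.random.default_rng(11)
        n_valid = 0
        for _ in range(400):
            h = make_random_history(rng)
            loopfree = pn.find_blocking_loop(h) is None
            ta = pn.assign_times(h)
            assert loopfree == ta.ok
            if ta.ok:
                n_valid += 1
                assert check_time_conditions(h, ta)
        assert 0 < n_valid < 400  # both outcomes exercised

    def test_is_valid_agrees_with_detector(self, cherry_forest):
        assert pn.is_valid(hist(cherry_forest, [pn.FlipEdge("a", "c")]))
        assert not pn.is_valid(hist(cherry_forest, [pn.FlipEdge("r", "a")]))
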