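"""Growth models: event sampling, forest bookkeeping, plausibility filter."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import parsinet as pn
from parsinet.simulate import (SimulationParams, exponential_rate_mle,
                               foster_evolve, powerlaw_exponent_mle,
                               sample_event)


def two_cycle():
    return pn.InteractionGraph.from_edges(["a", "b"], [("a", "b"), ("b", "a")],
                                          directed=True)


def forest_for(G):
    F = pn.DuplicationForest()
    for u in sorted(G.nodes):
        F.add_singleton(u)
    return F


class TestSeedGraph:
    def test_standard_seed_is_connected_with_exact_size(self):
        rng = np.random.default_rng(0)
        G = pn.random_seed_graph(10, 25, rng)
        assert len(G.nodes) == 10 and G.n_edges() == 25
        import networkx as nx
        assert nx.is_weakly_connected(G.g)

    def test_minimal_sizes(self):
        rng = np.random.default_rng(1)
        assert pn.random_seed_graph(2, 1, rng).n_edges() == 1
        G = pn.random_seed_graph(5, 4, rng)
        assert len(G.nodes) == 5 and G.n_edges() == 4  # spanning tree

    def test_infeasible_sizes_are_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(pn.InputError):
            pn.random_seed_graph(5, 3, rng)
        with pytest.raises(pn.InputError):
            pn.random_seed_graph(3, 7, rng)


class TestEvolve:
    def test_forced_duplication_splits_the_leaf(self):
        G = two_cycle()
        F = forest_for(G)
        params = SimulationParams(p_ndup=1, p_nloss=0, p_egain=0, p_eloss=0)
        pn.evolve(G, F, params, 1, np.random.default_rng(0))
        internal = [n for n in F.nodes.values() if not n.is_leaf]
        assert len(internal) == 1
        kids = F.children(internal[0].id)
        assert all(F[c].status == "present-leaf" for c in kids)
        assert set(G.nodes) == set(F.present_leaves())

    def test_present_leaves_track_graph_nodes(self):
        params = SimulationParams(rng_seed=0)
        rng = np.random.default_rng(3)
        G = pn.random_seed_graph(10, 25, rng)
        F = forest_for(G)
        pn.evolve(G, F, params, 120, rng)
        assert set(G.nodes) == set(F.present_leaves())

    def test_ddm_equals_dim_on_a_regular_graph(self):
        """With all degrees equal the degree weights are constant, so the
        degree-dependent and degree-independent models sample identically
        (chi-square on single-step event draws)."""
        G = pn.InteractionGraph.from_edges(
            ["a", "b", "c", "d"],
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")], directed=True)
        counts = {}
        for model in ("DDM", "DIM"):
            params = SimulationParams(model=model)
            rng = np.random.default_rng(99)
            c = {}
            for _ in range(4000):
                op, obj = sample_event(G, params, rng)
                key = (op, obj if isinstance(obj, str) else tuple(obj))
                c[key] = c.get(key, 0) + 1
            counts[model] = c
        keys = sorted(set(counts["DDM"]) | set(counts["DIM"]))
        table = [[counts[m].get(k, 0) for k in keys] for m in ("DDM", "DIM")]
        _, p, _, _ = chi2_contingency(table)
        assert p > 1e-3

    def test_operation_frequencies_match_probabilities(self):
        params = SimulationParams()
        rng = np.random.default_rng(17)
        G = pn.random_seed_graph(10, 25, rng)
        n = 10000
        ops = []
        for _ in range(n):
            op, _ = sample_event(G, params, rng)
            ops.append(op)
        for op, p in (("ndup", 0.35), ("nloss", 0.05),
                      ("egain", 0.30), ("eloss", 0.30)):
            freq = ops.count(op) / n
            sigma = (p * (1 - p) / n) ** 0.5
            assert abs(freq - p) < 3 * sigma + 1e-9

    def test_dying_network_signals_restart(self):
        G = two_cycle()
        F = forest_for(G)
        params = SimulationParams(p_ndup=0, p_nloss=1, p_egain=0, p_eloss=0)
        with pytest.raises(pn.SimulationRestart):
            pn.evolve(G, F, params, 5, np.random.default_rng(0))


class TestFoster:
    def test_full_retention_copies_the_neighbourhood(self):
        G = pn.InteractionGraph.from_edges(
            ["a", "b", "c"], [("a", "b"), ("b", "c"), ("c", "a")],
            directed=True)
        F = forest_for(G)
        params = SimulationParams(model="Foster", p_inkeep=1, p_outkeep=1,
                                  p_innovation=0)
        foster_evolve(G, F, params, 1, np.random.default_rng(0))
        dup = [n.id for n in F.nodes.values() if not n.is_leaf][0]
        orig, copy = f"{dup}.0", f"{dup}.1"
        assert set(G.g.predecessors(orig)) == set(G.g.predecessors(copy))
        assert set(G.g.successors(orig)) == set(G.g.successors(copy))

    def test_zero_retention_prunes_the_copy(self):
        G = pn.InteractionGraph.from_edges(
            ["a", "b", "c"], [("a", "b"), ("b", "c"), ("c", "a")],
            directed=True)
        F = forest_for(G)
        params = SimulationParams(model="Foster", p_inkeep=0, p_outkeep=0,
                                  p_innovation=0)
        foster_evolve(G, F, params, 1, np.random.default_rng(0))
        dup = [n.id for n in F.nodes.values() if not n.is_leaf][0]
        assert F[f"{dup}.1"].status == "absent-leaf"
        assert len(G.nodes) == 3

    def test_edge_retention_rate_approaches_p_outkeep(self):
        rng = np.random.default_rng(23)
        params = SimulationParams(model="Foster", p_inkeep=1.0, p_outkeep=0.6,
                                  p_innovation=0)
        kept = total = 0
        for _ in range(150):
            G = pn.random_seed_graph(6, 14, rng)
            F = forest_for(G)
            before = {u: G.k_out(u) for u in G.nodes}
            foster_evolve(G, F, params, 1, rng)
            dup = [n.id for n in F.nodes.values() if not n.is_leaf][0]
            copy = f"{dup}.1"
            total += before[dup]
            if copy in G.nodes:
                kept += G.k_out(copy)
        assert abs(kept / total - 0.6) < 0.1


class TestInstances:
    def test_zero_divergence_instance_is_the_identity(self):
        inst = pn.generate_instance(SimulationParams(ops_per_lineage=0,
                                                     rng_seed=4))
        assert inst.G1 == inst.X == inst.G2
        assert all(F[r].is_leaf for F in (inst.F1, inst.F2) for r in F.roots)

    def test_same_seed_is_bit_identical(self):
        p = SimulationParams(ops_per_lineage=30, rng_seed=12)
        a, b = pn.generate_instance(p), pn.generate_instance(p)
        assert a.X == b.X and a.G1 == b.G1 and a.G2 == b.G2
        assert set(a.F1.nodes) == set(b.F1.nodes)
        assert a.events1 == b.events1 and a.events2 == b.events2

    def test_true_event_history_constructs_the_extant_network(self):
        p = SimulationParams(ops_per_lineage=60, rng_seed=21)
        inst = pn.generate_instance(p)
        for lineage, G in ((1, inst.G1), (2, inst.G2)):
            h = inst.true_history(lineage)
            assert pn.constructs(h) == G
            assert pn.is_valid(h)

    def test_structural_invariants(self):
        inst = pn.generate_instance(SimulationParams(rng_seed=2))
        for F, G in ((inst.F1, inst.G1), (inst.F2, inst.G2)):
            F.validate()
            assert set(F.present_leaves()) == set(G.nodes)
            assert {F[r].homology_group for r in F.roots} == set(inst.X.nodes)


class TestPlausibilityFilter:
    def test_exponential_sample_is_accepted(self):
        rng = np.random.default_rng(31)
        hits = sum(1.0 <= exponential_rate_mle(rng.exponential(1 / 1.1, 200))
                   <= 1.2 for _ in range(40))
        assert hits > 20

    def test_powerlaw_sample_is_accepted(self):
        rng = np.random.default_rng(37)
        hits = 0
        for _ in range(40):
            x = rng.zipf(2.0, 300)
            hits += 1.8 <= powerlaw_exponent_mle(x) <= 2.2
        assert hits > 20

    def test_regular_degrees_are_rejected(self):
        G = pn.InteractionGraph.from_edges(
            ["a", "b", "c", "d"],
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")], directed=True)
        assert not pn.accept_instance(G)
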