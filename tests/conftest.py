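"""Shared fixtures: small hand-built forests and random-instance factories."""

from __future__ import annotations

import numpy as np
import pytest

import parsinet as pn


@pytest.fixture
def cherry_forest() -> pn.DuplicationForest:
    """One cherry r:(a, b) plus a singleton tree c."""
    F = pn.DuplicationForest()
    F.add_singleton("r")
    F.split_leaf("r", "a", "b")
    F.add_singleton("c")
    return F


def make_random_forest(rng: np.random.Generator, *, n_trees: int = 2,
                       max_splits: int = 3,
                       p_absent: float = 0.15) -> pn.DuplicationForest:
    F = pn.DuplicationForest()
    for t in range(int(rng.integers(1, n_trees + 1))):
        rid = f"t{t}"
        F.add_singleton(rid)
        leaves = [rid]
        for _ in range(int(rng.integers(0, max_splits + 1))):
            u = leaves[int(rng.integers(len(leaves)))]
            F.split_leaf(u, f"{u}.0", f"{u}.1")
            leaves.remove(u)
            leaves += [f"{u}.0", f"{u}.1"]
        for u in leaves:
            if rng.random() < p_absent:
                F.set_absent(u)
    return F


def make_random_graph(F: pn.DuplicationForest, rng: np.random.Generator, *,
                      directed: bool = False,
                      p_edge: float = 0.3) -> pn.InteractionGraph:
    pres = sorted(F.present_leaves())
    G = pn.InteractionGraph(directed=directed)
    for u in pres:
        G.add_node(u)
    for i, u in enumerate(pres):
        for v in pres[i + 1:]:
            if directed:
                if rng.random() < p_edge:
                    G.add_edge(u, v)
                if rng.random() < p_edge:
                    G.add_edge(v, u)
            elif rng.random() < p_edge:
                G.add_edge(u, v)
    return G


def make_random_history(rng: np.random.Generator, *, max_flips: int = 5
                        ) -> pn.NetworkHistory:
    F = make_random_forest(rng, n_trees=3, max_splits=3, p_absent=0.0)
    ids = sorted(F.nodes)
    flips = []
    if len(ids) >= 2:
        for _ in range(int(rng.integers(0, max_flips + 1))):
            a, b = rng.choice(len(ids), size=2, replace=False)
            flips.append(pn.FlipEdge(ids[int(a)], ids[int(b)]))
    return pn.NetworkHistory(F, flips)
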