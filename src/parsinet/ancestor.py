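"""Parsimonious common-ancestor network of two extant networks.

After a speciation event the two lineages evolve independently, so the DP
tables of the two duplication forests can be computed separately and then
combined: an ancestral interaction between homology groups ``r`` and ``q``
is placed exactly when creating it (one event at cost ``c_add``, which flips
the required parity in both lineages) is strictly cheaper than explaining
both extant interaction patterns without it:

    c_add + A_F1(r, q, odd) + A_F2(r, q, odd)  <  A_F1(r, q, even) + A_F2(r, q, even)

Ties yield no edge.  A group absent from one species contributes 0 to both
sides.  For directed networks the rule is applied per direction using the
corresponding parity bit.
"""

from __future__ import annotations

from typing import Optional

from .core import DuplicationForest, InteractionGraph
from .errors import InputError
from .parsimony import CostModel, DPTables, _s_selfloops, solve

#: The inferred ancestor is an interaction graph over homology-group ids.
AncestralGraph = InteractionGraph


def _group_roots(forest: DuplicationForest) -> dict[str, str]:
    groups: dict[str, str] = {}
    for r in forest.roots:
        g = forest[r].homology_group or r
        if g in groups:
            raise InputError(f"duplicate homology group {g!r} in one forest")
        groups[g] = r
    return groups


def infer_ancestor(F1: DuplicationForest, F2: DuplicationForest,
                   G1: InteractionGraph, G2: InteractionGraph,
                   costs: Optional[CostModel] = None,
                   *, ancestral_selfloops: bool = False) -> AncestralGraph:
    """Infer the ancestral network over the root homology groups.

    The forests must label their roots with homology groups; groups match
    across forests, and a group may be missing from one of them.  The rule is
    read directly off the first-pass DP tables (no loop breaking).  Ancestral
    self-loops are an extension of the printed pairwise rule via the
    self-flip recurrence; they are off by default.
    """
    costs = costs or CostModel()
    if G1.directed != G2.directed:
        raise InputError("extant graphs disagree on directedness")
    directed = G1.directed

    g1, g2 = _group_roots(F1), _group_roots(F2)
    groups = sorted(set(g1) | set(g2))

    _, t1 = solve(F1, G1, costs)
    _, t2 = solve(F2, G2, costs)

    X = InteractionGraph(directed=directed,
                         selfloops=ancestral_selfloops and not directed)
    for g in groups:
        X.add_node(g)

    def a(tables: DPTables, rootmap: dict[str, str], r: str, q: str,
          parity: int) -> float:
        if r not in rootmap or q not in rootmap:
            return 0.0
        return tables.a(rootmap[r], rootmap[q], parity)

    odd = 1
    for i, r in enumerate(groups):
        for q in groups[i + 1:]:
            if not directed:
                lhs = costs.c_add + a(t1, g1, r, q, odd) + a(t2, g2, r, q, odd)
                rhs = a(t1, g1, r, q, 0) + a(t2, g2, r, q, 0)
                if lhs < rhs:
                    X.add_edge(r, q)
            else:
                # bit 0 is the r -> q direction of the (r, q) table entry
                for src, dst, parity in ((r, q, 1), (q, r, 1)):
                    lhs = (costs.c_add
                           + a(t1, g1, src, dst, parity)
                           + a(t2, g2, src, dst, parity))
                    rhs = a(t1, g1, src, dst, 0) + a(t2, g2, src, dst, 0)
                    if lhs < rhs:
                        X.add_edge(src, dst)

    if ancestral_selfloops and not directed:
        for g in groups:
            lhs = costs.c_add
            rhs = 0.0
            for tables, rootmap in ((t1, g1), (t2, g2)):
                if g not in rootmap:
                    continue
                i = tables.idx[rootmap[g]]
                lhs += _s_selfloops(tables, i, 1)
                rhs += _s_selfloops(tables, i, 0)
            if lhs < rhs:
                X.add_edge(g, g)
    return X
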