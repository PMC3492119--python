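"""Brute-force reference implementations used by the test suite.

These enumerate the definitions directly (subsets of candidate flips, cyclic
orderings of flip sets) and exist purely as independent cross-checks for the
dynamic programs and the DFS loop detector.  They are exponential and only
usable on forests of roughly a dozen nodes.
"""

from __future__ import annotations

from itertools import combinations, permutations, product
from typing import Optional

from .core import (BOTH, FORWARD, REVERSE, UNDIRECTED, DuplicationForest,
                   FlipEdge, InteractionGraph, NetworkHistory, constructs,
                   is_valid)
from .errors import InputError


class BoundedSearchFailure(Exception):
    """No solution found within ``max_flips`` events."""


def _candidate_flips(forest: DuplicationForest, directed: bool,
                     selfloops: bool) -> list[FlipEdge]:
    """Flips that can affect an observable pair: both subtrees must contain a
    Present leaf and the endpoints must not be ancestor-related (such flips
    are 1-blocking loops and never appear in any valid or loop-relaxed
    optimum); at positive costs a flip touching no Present pair can always be
    dropped, so this pruning preserves every optimum."""
    ids = sorted(forest.nodes)
    has_present = {u: bool(forest.present_leaf_descendants(u)) for u in ids}
    cands: list[FlipEdge] = []
    for i, u in enumerate(ids):
        if selfloops and has_present[u]:
            cands.append(FlipEdge(u, u, UNDIRECTED if not directed else FORWARD))
        for v in ids[i + 1:]:
            if not (has_present[u] and has_present[v]):
                continue
            if forest.is_proper_ancestor(u, v) or forest.is_proper_ancestor(v, u):
                continue
            if directed:
                cands.append(FlipEdge(u, v, FORWARD))
                cands.append(FlipEdge(u, v, REVERSE))
            else:
                cands.append(FlipEdge(u, v, UNDIRECTED))
    return cands


def _has_short_blocking_loop(forest: DuplicationForest,
                             flips: tuple[FlipEdge, ...]) -> bool:
    """1- or 2-blocking loops only (the loops the DP recurrence excludes)."""
    for f in flips:
        if forest.is_proper_ancestor(f.a, f.b) or forest.is_proper_ancestor(f.b, f.a):
            return True
    for f, g in combinations(flips, 2):
        for (u0, v0) in ((f.a, f.b), (f.b, f.a)):
            for (u1, v1) in ((g.a, g.b), (g.b, g.a)):
                if forest.is_proper_ancestor(u1, v0) and forest.is_proper_ancestor(u0, v1):
                    return True
    return False


def _flip_mask(forest: DuplicationForest, f: FlipEdge, pair_bit: dict,
               directed: bool, selfloops: bool) -> int:
    """Bitmask over extant pairs toggled by one flip (the parity rule)."""
    da = forest.present_leaf_descendants(f.a)
    db = forest.present_leaf_descendants(f.b)
    touched = set()
    if not directed:
        for u in da:
            for v in db:
                if u == v and not selfloops:
                    continue
                touched.add((u, v) if u <= v else (v, u))
    else:
        if f.orientation in (FORWARD, BOTH):
            touched.update((u, v) for u in da for v in db
                           if u != v or selfloops)
        if f.orientation in (REVERSE, BOTH):
            touched.update((u, v) for u in db for v in da
                           if u != v or selfloops)
    mask = 0
    for p in touched:
        mask ^= 1 << pair_bit[p]
    return mask


def brute_force_min_flips(forest: DuplicationForest, G: InteractionGraph,
                          max_flips: int = 6, *, require_valid: bool = True,
                          selfloops: bool = False
                          ) -> tuple[int, tuple[FlipEdge, ...]]:
    """Exhaustive minimum-event search at unit costs.

    Iterative deepening over subsets of candidate flips by increasing size;
    returns the smallest subset that constructs ``G`` and either is a fully
    valid history (``require_valid``) or merely avoids 1-/2-blocking loops
    (the dynamic program's relaxation, giving its lower bound).  Parity is
    tracked as XOR over bitmasks of affected extant pairs, so only the rare
    parity-matching subsets pay for a full validity check.
    """
    if not set(G.nodes) <= set(forest.present_leaves()):
        raise InputError("graph contains a node that is not a Present leaf")
    allow_self = selfloops or G.selfloops
    cands = _candidate_flips(forest, G.directed, allow_self)

    leaves = sorted(forest.present_leaves())
    if G.directed:
        pairs = [(u, v) for u in leaves for v in leaves
                 if u != v or allow_self]
    else:
        pairs = [(u, v) for i, u in enumerate(leaves) for v in leaves[i:]
                 if u != v or allow_self]
    pair_bit = {p: i for i, p in enumerate(pairs)}
    target = 0
    for u, v in G.g.edges:
        key = (u, v) if G.directed or u <= v else (v, u)
        target ^= 1 << pair_bit[key]

    masks = [_flip_mask(forest, f, pair_bit, G.directed, allow_self)
             for f in cands]
    # incompatibility: picking j after i would create a 2-blocking loop
    # (1-loops are already excluded from the candidate set)
    m = len(cands)
    incompat = [0] * m
    for i in range(m):
        for j in range(i + 1, m):
            if _has_short_blocking_loop(forest, (cands[i], cands[j])):
                incompat[i] |= 1 << j
                incompat[j] |= 1 << i

    best: list = []

    def dfs(start: int, need: int, acc: int, banned: int,
            chosen: tuple) -> bool:
        if need == 0:
            if acc != target:
                return False
            if require_valid:
                hist = NetworkHistory(forest, list(chosen),
                                      directed=G.directed,
                                      selfloops=allow_self)
                if not is_valid(hist):
                    return False
            best.append(chosen)
            return True
        for j in range(start, m - need + 1):
            if banned >> j & 1:
                continue
            if dfs(j + 1, need - 1, acc ^ masks[j], banned | incompat[j],
                   chosen + (cands[j],)):
                return True
        return False

    for k in range(max_flips + 1):
        if dfs(0, k, 0, 0, ()):
            return k, best[0]
    raise BoundedSearchFailure(f"no solution with <= {max_flips} flips")


def brute_force_blocking_check(history: NetworkHistory,
                               k_max: Optional[int] = None) -> bool:
    """Verbatim enumeration of the blocking-loop definition.

    Tries every subset of flips up to size ``k_max``, every cyclic ordering
    and every designation of the two endpoints as (descendant end, ancestor
    end), and tests that each flip's ancestor end properly dominates the next
    flip's descendant end around the cycle.
    """
    F = history.forest
    flips = list(history.flips)
    if k_max is None:
        k_max = len(flips)
    for k in range(1, min(k_max, len(flips)) + 1):
        for subset in combinations(flips, k):
            first, rest = subset[0], subset[1:]
            for order in permutations(rest):
                seq = (first,) + order
                for orient in product((0, 1), repeat=k):
                    # orientation bit 0: (u_i, v_i) = (a, b); 1: swapped
                    uv = [(f.b, f.a) if o else (f.a, f.b)
                          for f, o in zip(seq, orient)]
                    if all(F.is_proper_ancestor(uv[(i + 1) % k][0], uv[i][1])
                           for i in range(k)):
                        return True
    return False
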