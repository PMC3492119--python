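"""Greedy removal of blocking loops from a DP solution.

The dynamic program excludes 1- and 2-blocking loops structurally but may
return a flip set containing a longer loop.  Whenever the backtracked
solution contains a blocking loop, one of the loop's flips is chosen
uniformly at random, its node pair is forbidden, and the DP is rerun; the
forbidden set grows strictly, so at most O(n²) iterations are needed (in the
degenerate worst case every flip ends up at a leaf pair, which is always
valid).  The first-pass DP cost is kept as a lower bound on the fully valid
optimum, giving a per-instance optimality certificate when the final cost
matches it.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .core import (DuplicationForest, InteractionGraph, NetworkHistory,
                   find_blocking_loop)
from .parsimony import CostModel, ReconstructionResult, backtrack, solve


def reconstruct_valid_history(forest: DuplicationForest, G: InteractionGraph,
                              costs: Optional[CostModel] = None,
                              rng_seed: int = 0,
                              forbidden: Iterable = ()) -> ReconstructionResult:
    """Minimum-cost *valid* history constructing ``G`` (greedy loop breaking).

    ``rng_seed`` drives the random choice of which flip on a discovered loop
    to forbid; the same seed yields an identical reconstruction.
    """
    rng = np.random.default_rng(rng_seed)
    costs = costs or CostModel()
    forb: set[frozenset] = {frozenset(p) for p in forbidden}

    cost, tables = solve(forest, G, costs, forb)
    lower = cost
    flips = backtrack(tables)
    iterations = 0
    while True:
        hist = NetworkHistory(forest, flips, directed=G.directed,
                              selfloops=G.selfloops)
        loop = find_blocking_loop(hist)
        if loop is None:
            break
        victim = loop[int(rng.integers(len(loop)))]
        forb.add(frozenset((victim.a, victim.b)))
        cost, tables = solve(forest, G, costs, forb)
        flips = backtrack(tables)
        iterations += 1
    return ReconstructionResult(flips=flips, cost=float(cost),
                                lower_bound=float(lower),
                                iterations=iterations,
                                forbidden_pairs=frozenset(forb),
                                seed=rng_seed)
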