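"""Minimum-cost flip-set dynamic programs.

Given a duplication forest and an extant network the intertwined recurrences
``S``/``A`` compute the cheapest set of interaction flip events constructing
the network while excluding 1- and 2-blocking loops (longer loops are
permitted, so the result is a lower bound on the fully valid optimum; see
:mod:`parsinet.loopbreak`).  ``S(u, f)`` scores the subtree below ``u`` under
parity state ``f``; ``A(u, v, f)`` scores the bipartite family of interactions
between the subtrees below ``u`` and ``v``:

    S(u, f) = S(u_L, f) + S(u_R, f) + A(u_L, u_R, f)

    A(u, v, f) = min( A(u_L, v, f) + A(u_R, v, f),
                      A(u, v_L, f) + A(u, v_R, f),
                      c(f) + A(u_L, v, f̄) + A(u_R, v, f̄),
                      c(f) + A(u, v_L, f̄) + A(u, v_R, f̄) )

with leaf bases S = 0 and A(a, b, f) = f(a, b) · c(f).  The parity state
records whether an even or odd number of flips sit above the current pair on
the two root paths: a flip placed at even parity creates an interaction
(cost ``c_add``); at odd parity it deletes one (``c_loss``).  Variants cover
self-loops (a self-flip at ``u`` toggles every interaction among u's
descendants), directed graphs (independent forward/backward parity bits) and
a branch-length penalty α·δ(u, v) added to each flip between nodes whose
existence intervals are disjoint.  Pairs involving only Absent leaves cost
nothing: lost genes impose no observable constraint.

The tables are filled bottom-up over all subtree-disjoint node pairs in
O(n²) time and space (numba-compiled kernels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from numba import njit

from .core import (BOTH, FORWARD, REVERSE, UNDIRECTED, DuplicationForest,
                   FlipEdge, InteractionGraph, TreeNode)
from .errors import ConfigError, InputError

_TOL = 1e-9


@dataclass(frozen=True)
class CostModel:
    """Event costs: ``c_add`` per interaction creation, ``c_loss`` per
    deletion, and ``alpha`` scaling the existence-interval penalty δ
    (``alpha = inf`` turns branch lengths into hard constraints)."""

    c_add: float = 1.0
    c_loss: float = 1.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.c_add < 0 or self.c_loss < 0 or self.alpha < 0:
            raise ConfigError("costs must be nonnegative")

    def c(self, parity: int) -> float:
        return self.c_add if parity == 0 else self.c_loss


def branch_penalty(u: TreeNode, v: TreeNode) -> float:
    """Gap δ(u, v) between the existence intervals [t_c, t_d) of two nodes:
    0 when they overlap, otherwise the distance between them."""
    for node in (u, v):
        if node.t_c is None:
            raise ConfigError(f"node {node.id!r} carries no creation time")
    tud = u.t_d if u.t_d is not None else math.inf
    tvd = v.t_d if v.t_d is not None else math.inf
    if tud < v.t_c:
        return v.t_c - tud
    if tvd < u.t_c:
        return u.t_c - tvd
    return 0.0


# ---------------------------------------------------------------------------
# DP context and tables
# ---------------------------------------------------------------------------

@dataclass
class DPTables:
    """Filled memo tables plus the index structures needed to read them back."""

    forest: DuplicationForest
    graph: InteractionGraph
    costs: CostModel
    ids: list[str]
    idx: dict[str, int]
    left: np.ndarray
    right: np.ndarray
    present: np.ndarray
    tin: np.ndarray
    tout: np.ndarray
    adj: np.ndarray
    forb: np.ndarray
    pen: np.ndarray
    A: np.ndarray               # (n, n, n_parities)
    directed: bool
    selfloops: bool
    forbidden: frozenset
    total: float = math.nan
    s_memo: dict = field(default_factory=dict)   # self-loop variant S'(u, p)
    desc_cache: dict = field(default_factory=dict)

    def a(self, r: str, q: str, parity: int) -> float:
        """Table lookup by node id; parity is 1 bit (undirected) or 2 bits
        (directed, bit0 = r->q direction)."""
        return float(self.A[self.idx[r], self.idx[q], parity])


def _build_context(forest: DuplicationForest, G: InteractionGraph,
                   costs: CostModel, forbidden: Iterable) -> DPTables:
    present_set = set(forest.present_leaves())
    if not set(G.nodes) <= present_set:
        extra = sorted(set(G.nodes) - present_set)
        raise InputError(f"graph nodes are not Present leaves: {extra[:5]}")
    ids = sorted(forest.nodes)
    idx = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    present = np.zeros(n, dtype=np.bool_)
    for nid, node in forest.nodes.items():
        i = idx[nid]
        if not node.is_leaf:
            left[i] = idx[node.left]
            right[i] = idx[node.right]
        elif node.present:
            present[i] = True
    intervals = forest.euler_intervals()
    tin = np.zeros(n, dtype=np.int64)
    tout = np.zeros(n, dtype=np.int64)
    for nid, (ti, to) in intervals.items():
        tin[idx[nid]] = ti
        tout[idx[nid]] = to
    adj = np.zeros((n, n), dtype=np.uint8)
    for u, v in G.g.edges:
        adj[idx[u], idx[v]] = 1
        if not G.directed:
            adj[idx[v], idx[u]] = 1
    forb = np.zeros((n, n), dtype=np.bool_)
    fset = set()
    for pair in forbidden:
        a, b = tuple(pair)
        forb[idx[a], idx[b]] = True
        forb[idx[b], idx[a]] = True
        fset.add(frozenset((a, b)) if a != b else frozenset((a,)))
    pen = _penalty_matrix(forest, ids, idx, costs)
    return DPTables(forest=forest, graph=G, costs=costs, ids=ids, idx=idx,
                    left=left, right=right, present=present, tin=tin,
                    tout=tout, adj=adj, forb=forb, pen=pen,
                    A=np.empty(0), directed=G.directed, selfloops=G.selfloops,
                    forbidden=frozenset(fset))


def _penalty_matrix(forest: DuplicationForest, ids: list[str],
                    idx: dict[str, int], costs: CostModel) -> np.ndarray:
    n = len(ids)
    if costs.alpha == 0:
        return np.zeros((n, n))
    tc = np.empty(n)
    td = np.empty(n)
    for nid in ids:
        node = forest.nodes[nid]
        if node.t_c is None:
            raise ConfigError(
                "alpha > 0 requires creation/duplication times on every node "
                f"(missing on {nid!r}); load forests with branch lengths")
        tc[idx[nid]] = node.t_c
        td[idx[nid]] = node.t_d if node.t_d is not None else math.inf
    delta = np.maximum(tc[None, :] - td[:, None], tc[:, None] - td[None, :])
    delta = np.maximum(delta, 0.0)
    if math.isinf(costs.alpha):
        return np.where(delta > 0, math.inf, 0.0)
    return costs.alpha * delta


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill_undirected(po, left, right, present, tin, tout, adj, forb,
                     c_add, c_loss, pen):  # pragma: no cover - compiled
    n = po.shape[0]
    A = np.full((n, n, 2), np.inf)
    for oi in range(n):
        u = po[oi]
        ul, ur = left[u], right[u]
        for oj in range(oi):
            v = po[oj]
            if (tin[u] < tin[v] and tin[v] <= tout[u]) or \
               (tin[v] < tin[u] and tin[u] <= tout[v]):
                continue
            vl, vr = left[v], right[v]
            if ul < 0 and vl < 0:
                for p in range(2):
                    if present[u] and present[v] and (adj[u, v] ^ p):
                        if forb[u, v]:
                            val = np.inf
                        elif p == 0:
                            val = c_add
                        else:
                            val = c_loss
                    else:
                        val = 0.0
                    A[u, v, p] = val
                    A[v, u, p] = val
                continue
            d = pen[u, v]
            for p in range(2):
                best = np.inf
                if ul >= 0:
                    cand = A[ul, v, p] + A[ur, v, p]
                    if cand < best:
                        best = cand
                if vl >= 0:
                    cand = A[u, vl, p] + A[u, vr, p]
                    if cand < best:
                        best = cand
                if not forb[u, v]:
                    fc = (c_add if p == 0 else c_loss) + d
                    q = 1 - p
                    if ul >= 0:
                        cand = fc + A[ul, v, q] + A[ur, v, q]
                        if cand < best:
                            best = cand
                    if vl >= 0:
                        cand = fc + A[u, vl, q] + A[u, vr, q]
                        if cand < best:
                            best = cand
                A[u, v, p] = best
                A[v, u, p] = best
    return A


@njit(cache=True)
def _fill_directed(po, left, right, present, tin, tout, adj, forb,
                   c_add, c_loss, pen):  # pragma: no cover - compiled
    n = po.shape[0]
    A = np.full((n, n, 4), np.inf)
    swap = np.array([0, 2, 1, 3], dtype=np.int64)
    for oi in range(n):
        u = po[oi]
        ul, ur = left[u], right[u]
        for oj in range(oi):
            v = po[oj]
            if (tin[u] < tin[v] and tin[v] <= tout[u]) or \
               (tin[v] < tin[u] and tin[u] <= tout[v]):
                continue
            vl, vr = left[v], right[v]
            if ul < 0 and vl < 0:
                for p in range(4):
                    if present[u] and present[v]:
                        pf = p & 1
                        pb = (p >> 1) & 1
                        need_f = adj[u, v] ^ pf
                        need_b = adj[v, u] ^ pb
                        if (need_f or need_b) and forb[u, v]:
                            val = np.inf
                        else:
                            val = 0.0
                            if need_f:
                                val += c_loss if pf else c_add
                            if need_b:
                                val += c_loss if pb else c_add
                    else:
                        val = 0.0
                    A[u, v, p] = val
                    A[v, u, swap[p]] = val
                continue
            d = pen[u, v]
            for p in range(4):
                best = np.inf
                for e in range(4):
                    if e != 0 and forb[u, v]:
                        continue
                    fc = 0.0
                    if e & 1:
                        fc += (c_loss if (p & 1) else c_add) + d
                    if e & 2:
                        fc += (c_loss if (p & 2) else c_add) + d
                    q = p ^ e
                    if ul >= 0:
                        cand = fc + A[ul, v, q] + A[ur, v, q]
                        if cand < best:
                            best = cand
                    if vl >= 0:
                        cand = fc + A[u, vl, q] + A[u, vr, q]
                        if cand < best:
                            best = cand
                A[u, v, p] = best
                A[v, u, swap[p]] = best
    return A


# ---------------------------------------------------------------------------
# Public solvers
# ---------------------------------------------------------------------------

def _postorder_indices(tables: DPTables) -> np.ndarray:
    order = tables.forest.postorder()
    return np.array([tables.idx[nid] for nid in order], dtype=np.int64)


def _root_pairs(tables: DPTables) -> list[tuple[int, int]]:
    roots = sorted(tables.forest.roots)
    return [(tables.idx[r], tables.idx[q])
            for i, r in enumerate(roots) for q in roots[i + 1:]]


def _fill(tables: DPTables) -> None:
    po = _postorder_indices(tables)
    kern = _fill_directed if tables.directed else _fill_undirected
    tables.A = kern(po, tables.left, tables.right, tables.present,
                    tables.tin, tables.tout, tables.adj, tables.forb,
                    float(tables.costs.c_add), float(tables.costs.c_loss),
                    tables.pen)


def min_flip_cost(forest: DuplicationForest, G: InteractionGraph,
                  costs: Optional[CostModel] = None,
                  forbidden: Iterable = ()) -> tuple[float, DPTables]:
    """Minimum flip cost for an undirected network without self-loops.

    Returns the forest total Σ_r S(r, even) + Σ_{r<q} A(r, q, even) and the
    filled tables (for :func:`backtrack` and the ancestor rule).  Flip options
    on pairs listed in ``forbidden`` are disallowed.
    """
    if G.directed:
        raise InputError("graph is directed; use min_flip_cost_directed")
    costs = costs or CostModel()
    tables = _build_context(forest, G, costs, forbidden)
    _fill(tables)
    total = 0.0
    for i in range(len(tables.ids)):
        if tables.left[i] >= 0:
            total += tables.A[tables.left[i], tables.right[i], 0]
    for r, q in _root_pairs(tables):
        total += tables.A[r, q, 0]
    tables.total = float(total)
    return tables.total, tables


def min_flip_cost_directed(forest: DuplicationForest, G: InteractionGraph,
                           costs: Optional[CostModel] = None,
                           forbidden: Iterable = ()) -> tuple[float, DPTables]:
    """Directed variant: a flip may run u->v, v->u, or both (two events);
    the parity state keeps one bit per direction."""
    if not G.directed:
        raise InputError("graph is undirected; use min_flip_cost")
    if G.selfloops:
        raise ConfigError("directed graphs with self-loops are not supported")
    costs = costs or CostModel()
    tables = _build_context(forest, G, costs, forbidden)
    _fill(tables)
    total = 0.0
    for i in range(len(tables.ids)):
        if tables.left[i] >= 0:
            total += tables.A[tables.left[i], tables.right[i], 0]
    for r, q in _root_pairs(tables):
        total += tables.A[r, q, 0]
    tables.total = float(total)
    return tables.total, tables


def _s_selfloops(tables: DPTables, i: int, p: int) -> float:
    """S'(u, f): subtree cost when a self-flip at u may toggle every
    interaction (self-loops included) among u's descendants."""
    key = (i, p)
    if key in tables.s_memo:
        return tables.s_memo[key][0]
    c = tables.costs
    if tables.left[i] < 0:
        need = tables.present[i] and (tables.adj[i, i] ^ p)
        if need and tables.forb[i, i]:
            val, choice = math.inf, 0
        else:
            val, choice = (c.c(p) if need else 0.0), 0
    else:
        l, r = tables.left[i], tables.right[i]
        keep = (_s_selfloops(tables, l, p) + _s_selfloops(tables, r, p)
                + tables.A[l, r, p])
        q = 1 - p
        if tables.forb[i, i]:
            flip = math.inf
        else:
            flip = (c.c(p) + _s_selfloops(tables, l, q)
                    + _s_selfloops(tables, r, q) + tables.A[l, r, q])
        if keep <= flip + _TOL:
            val, choice = keep, 0
        else:
            val, choice = flip, 1
    tables.s_memo[key] = (val, choice)
    return val


def min_flip_cost_selfloops(forest: DuplicationForest, G: InteractionGraph,
                            costs: Optional[CostModel] = None,
                            forbidden: Iterable = ()) -> tuple[float, DPTables]:
    """Undirected variant admitting self-loops (homodimers) via self-flips."""
    if G.directed:
        raise ConfigError("directed graphs with self-loops are not supported")
    costs = costs or CostModel()
    tables = _build_context(forest, G, costs, forbidden)
    _fill(tables)
    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        total = sum(_s_selfloops(tables, tables.idx[r], 0)
                    for r in sorted(forest.roots))
    finally:
        sys.setrecursionlimit(old)
    for r, q in _root_pairs(tables):
        total += tables.A[r, q, 0]
    tables.total = float(total)
    return tables.total, tables


def solve(forest: DuplicationForest, G: InteractionGraph,
          costs: Optional[CostModel] = None,
          forbidden: Iterable = ()) -> tuple[float, DPTables]:
    """Dispatch to the variant matching the graph's flags."""
    if G.directed:
        return min_flip_cost_directed(forest, G, costs, forbidden)
    if G.selfloops:
        return min_flip_cost_selfloops(forest, G, costs, forbidden)
    return min_flip_cost(forest, G, costs, forbidden)


# ---------------------------------------------------------------------------
# Backtracking
# ---------------------------------------------------------------------------

def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _TOL * max(1.0, abs(a), abs(b))


def backtrack(tables: DPTables) -> list[FlipEdge]:
    """Recover one minimum-cost flip set from filled tables.

    Ties in the recurrence minima are broken in a fixed option order
    (split-u, split-v, then the flip-bearing options), so the result is
    deterministic for a given instance.
    """
    if tables.A.size == 0:
        raise InputError("tables have not been filled")
    flips: list[FlipEdge] = []
    stack: list[tuple[int, int, int]] = []

    if tables.selfloops:
        for r in sorted(tables.forest.roots):
            _backtrack_s(tables, tables.idx[r], 0, flips, stack)
    else:
        for i in range(len(tables.ids)):
            if tables.left[i] >= 0:
                stack.append((tables.left[i], tables.right[i], 0))
    for r, q in _root_pairs(tables):
        stack.append((r, q, 0))

    while stack:
        u, v, p = stack.pop()
        if tables.directed:
            _step_directed(tables, u, v, p, flips, stack)
        else:
            _step_undirected(tables, u, v, p, flips, stack)
    return flips


def _backtrack_s(tables: DPTables, i: int, p: int, flips: list[FlipEdge],
                 stack: list[tuple[int, int, int]]) -> None:
    c = tables.costs
    todo = [(i, p)]
    while todo:
        i, p = todo.pop()
        _s_selfloops(tables, i, p)
        _, choice = tables.s_memo[(i, p)]
        if tables.left[i] < 0:
            if tables.present[i] and (tables.adj[i, i] ^ p):
                nid = tables.ids[i]
                flips.append(FlipEdge(nid, nid, UNDIRECTED))
            continue
        l, r = tables.left[i], tables.right[i]
        if choice == 1:
            nid = tables.ids[i]
            flips.append(FlipEdge(nid, nid, UNDIRECTED))
            p = 1 - p
        todo.append((l, p))
        todo.append((r, p))
        stack.append((l, r, p))


def _step_undirected(tables: DPTables, u: int, v: int, p: int,
                     flips: list[FlipEdge], stack: list) -> None:
    A = tables.A
    val = A[u, v, p]
    if val == 0.0 and p == 0 and not _block_has_edges(tables, u, v):
        return  # nothing to explain below this pair
    ul, ur = tables.left[u], tables.right[u]
    vl, vr = tables.left[v], tables.right[v]
    if ul < 0 and vl < 0:
        if tables.present[u] and tables.present[v] and (tables.adj[u, v] ^ p):
            flips.append(FlipEdge(tables.ids[u], tables.ids[v], UNDIRECTED))
        return
    if ul >= 0 and _close(val, A[ul, v, p] + A[ur, v, p]):
        stack.append((ul, v, p))
        stack.append((ur, v, p))
        return
    if vl >= 0 and _close(val, A[u, vl, p] + A[u, vr, p]):
        stack.append((u, vl, p))
        stack.append((u, vr, p))
        return
    fc = tables.costs.c(p) + tables.pen[u, v]
    q = 1 - p
    if not tables.forb[u, v]:
        if ul >= 0 and _close(val, fc + A[ul, v, q] + A[ur, v, q]):
            flips.append(FlipEdge(tables.ids[u], tables.ids[v], UNDIRECTED))
            stack.append((ul, v, q))
            stack.append((ur, v, q))
            return
        if vl >= 0 and _close(val, fc + A[u, vl, q] + A[u, vr, q]):
            flips.append(FlipEdge(tables.ids[u], tables.ids[v], UNDIRECTED))
            stack.append((u, vl, q))
            stack.append((u, vr, q))
            return
    raise AssertionError("backtracking failed to reproduce the DP value")


_ORIENT = {1: FORWARD, 2: REVERSE, 3: BOTH}


def _step_directed(tables: DPTables, u: int, v: int, p: int,
                   flips: list[FlipEdge], stack: list) -> None:
    A = tables.A
    val = A[u, v, p]
    if val == 0.0 and p == 0 and not _block_has_edges(tables, u, v):
        return
    ul, ur = tables.left[u], tables.right[u]
    vl, vr = tables.left[v], tables.right[v]
    if ul < 0 and vl < 0:
        if tables.present[u] and tables.present[v]:
            need_f = tables.adj[u, v] ^ (p & 1)
            need_b = tables.adj[v, u] ^ ((p >> 1) & 1)
            e = (1 if need_f else 0) | (2 if need_b else 0)
            if e:
                flips.append(FlipEdge(tables.ids[u], tables.ids[v], _ORIENT[e]))
        return
    for e in range(4):
        if e != 0 and tables.forb[u, v]:
            continue
        fc = 0.0
        if e & 1:
            fc += (tables.costs.c_loss if (p & 1) else tables.costs.c_add) \
                + tables.pen[u, v]
        if e & 2:
            fc += (tables.costs.c_loss if (p & 2) else tables.costs.c_add) \
                + tables.pen[u, v]
        q = p ^ e
        if ul >= 0 and _close(val, fc + A[ul, v, q] + A[ur, v, q]):
            if e:
                flips.append(FlipEdge(tables.ids[u], tables.ids[v], _ORIENT[e]))
            stack.append((ul, v, q))
            stack.append((ur, v, q))
            return
        if vl >= 0 and _close(val, fc + A[u, vl, q] + A[u, vr, q]):
            if e:
                flips.append(FlipEdge(tables.ids[u], tables.ids[v], _ORIENT[e]))
            stack.append((u, vl, q))
            stack.append((u, vr, q))
            return
    raise AssertionError("backtracking failed to reproduce the DP value")


def _block_has_edges(tables: DPTables, u: int, v: int) -> bool:
    """Whether any observed interaction crosses between the two subtrees."""
    F, ids = tables.forest, tables.ids
    for i in (u, v):
        if i not in tables.desc_cache:
            tables.desc_cache[i] = [tables.idx[x]
                                    for x in F.present_leaf_descendants(ids[i])]
    du = tables.desc_cache[u]
    dv = tables.desc_cache[v]
    if not du or not dv:
        return False
    sub = tables.adj[np.ix_(du, dv)]
    if sub.any():
        return True
    if tables.directed:
        return bool(tables.adj[np.ix_(dv, du)].any())
    return False


@dataclass
class ReconstructionResult:
    """Outcome of a full reconstruction (DP + blocking-loop removal)."""

    flips: list[FlipEdge]
    cost: float
    lower_bound: float
    iterations: int
    forbidden_pairs: frozenset
    seed: Optional[int] = None

    @property
    def relative_excess(self) -> float:
        if self.lower_bound == 0:
            return 0.0
        return (self.cost - self.lower_bound) / self.lower_bound
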