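"""History-graph data model: duplication forests, flip edges and validity.

A *duplication forest* is a collection of rooted binary trees whose internal
nodes are gene-duplication events and whose leaves are extant (Present) or
lost (Absent) genes.  Interaction gain/loss events are *flip edges* placed
between forest nodes: an extant pair of genes ``(u, v)`` interacts exactly
when an odd number of flips join the root path of ``u`` to the root path of
``v``.  A forest plus a set of flips is a *network history*; it is valid iff
the events admit a consistent time assignment, which holds iff the flips
contain no *blocking loop* — a cyclic chain of flips ``{u_i, v_i}`` in which
each ``u_{i+1}`` is a proper ancestor of ``v_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

from .errors import InputError, ModelError

# Flip-edge orientations.
UNDIRECTED = "undirected"
FORWARD = "forward"  # a -> b
REVERSE = "reverse"  # b -> a
BOTH = "both"

INTERNAL = "internal"
PRESENT_LEAF = "present-leaf"
ABSENT_LEAF = "absent-leaf"


@dataclass
class TreeNode:
    """One node of a duplication tree.

    Internal nodes represent a duplication of the gene into the two children;
    leaves are extant (present) or lost (absent) genes.  ``t_c``/``t_d`` are
    optional real-valued creation/duplication times derived from branch
    lengths (used by the branch-length penalty); the integer times produced by
    :func:`assign_times` are kept separate.
    """

    id: str
    parent: Optional[str] = None
    left: Optional[str] = None
    right: Optional[str] = None
    present: bool = True
    homology_group: Optional[str] = None
    species: Optional[str] = None
    t_c: Optional[float] = None
    t_d: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def status(self) -> str:
        if not self.is_leaf:
            return INTERNAL
        return PRESENT_LEAF if self.present else ABSENT_LEAF


class DuplicationForest:
    """A set of disjoint rooted binary duplication trees with unique node ids."""

    def __init__(self) -> None:
        self.nodes: dict[str, TreeNode] = {}
        self.roots: list[str] = []

    # -- construction -----------------------------------------------------

    def add_singleton(self, leaf_id: str, *, group: Optional[str] = None,
                      present: bool = True, species: Optional[str] = None) -> TreeNode:
        """Add a new single-leaf tree (one extant or lost gene, no duplications)."""
        if leaf_id in self.nodes:
            raise InputError(f"duplicate node id {leaf_id!r}")
        node = TreeNode(id=leaf_id, present=present,
                        homology_group=group if group is not None else leaf_id,
                        species=species)
        self.nodes[leaf_id] = node
        self.roots.append(leaf_id)
        return node

    def add_node(self, node: TreeNode, *, is_root: bool = False) -> None:
        if node.id in self.nodes:
            raise InputError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        if is_root:
            self.roots.append(node.id)

    def split_leaf(self, leaf_id: str, left_id: str, right_id: str) -> tuple[TreeNode, TreeNode]:
        """Turn a leaf into a duplication node with two fresh present children."""
        node = self[leaf_id]
        if not node.is_leaf:
            raise InputError(f"{leaf_id!r} is not a leaf")
        for cid in (left_id, right_id):
            if cid in self.nodes:
                raise InputError(f"duplicate node id {cid!r}")
        kids = []
        for cid in (left_id, right_id):
            child = TreeNode(id=cid, parent=leaf_id, present=True,
                             homology_group=node.homology_group, species=node.species)
            self.nodes[cid] = child
            kids.append(child)
        node.left, node.right = left_id, right_id
        return kids[0], kids[1]

    def set_absent(self, leaf_id: str) -> None:
        node = self[leaf_id]
        if not node.is_leaf:
            raise InputError(f"{leaf_id!r} is not a leaf")
        node.present = False

    # -- queries ----------------------------------------------------------

    def __getitem__(self, node_id: str) -> TreeNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise InputError(f"unknown node id {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, node_id: str) -> tuple[str, ...]:
        node = self[node_id]
        return () if node.is_leaf else (node.left, node.right)

    def leaves(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.is_leaf]

    def present_leaves(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.status == PRESENT_LEAF]

    def root_of(self, node_id: str) -> str:
        u = self[node_id]
        while u.parent is not None:
            u = self[u.parent]
        return u.id

    def root_path(self, node_id: str) -> list[str]:
        """Path from ``node_id`` up to (and including) its root."""
        path = [node_id]
        u = self[node_id]
        while u.parent is not None:
            path.append(u.parent)
            u = self[u.parent]
        return path

    def is_proper_ancestor(self, u: str, v: str) -> bool:
        """True iff ``u`` lies strictly above ``v`` on v's root path."""
        if u == v:
            return False
        self[u]
        w = self[v]
        while w.parent is not None:
            if w.parent == u:
                return True
            w = self[w.parent]
        return False

    def subtree(self, node_id: str) -> Iterator[str]:
        stack = [node_id]
        while stack:
            nid = stack.pop()
            yield nid
            node = self[nid]
            if not node.is_leaf:
                stack.extend((node.right, node.left))

    def present_leaf_descendants(self, node_id: str) -> list[str]:
        return [nid for nid in self.subtree(node_id)
                if self.nodes[nid].status == PRESENT_LEAF]

    def postorder(self) -> list[str]:
        """All nodes, children before parents; deterministic (roots sorted)."""
        order: list[str] = []
        for r in sorted(self.roots):
            stack: list[tuple[str, bool]] = [(r, False)]
            while stack:
                nid, expanded = stack.pop()
                node = self.nodes[nid]
                if expanded or node.is_leaf:
                    order.append(nid)
                else:
                    stack.append((nid, True))
                    stack.append((node.right, False))
                    stack.append((node.left, False))
        return order

    def euler_intervals(self) -> dict[str, tuple[int, int]]:
        """Entry/exit indices of a DFS; ``u`` properly contains ``v`` iff
        ``tin[u] < tin[v] <= tout[u]`` (constant-time ancestor queries)."""
        tin: dict[str, tuple[int, int]] = {}
        clock = 0
        enter: dict[str, int] = {}
        for r in sorted(self.roots):
            stack: list[tuple[str, bool]] = [(r, False)]
            while stack:
                nid, expanded = stack.pop()
                node = self.nodes[nid]
                if expanded:
                    tin[nid] = (enter[nid], clock)
                    continue
                clock += 1
                enter[nid] = clock
                stack.append((nid, True))
                if not node.is_leaf:
                    stack.append((node.right, False))
                    stack.append((node.left, False))
        return tin

    def validate(self) -> None:
        seen: set[str] = set()
        for r in self.roots:
            if self[r].parent is not None:
                raise InputError(f"root {r!r} has a parent")
            for nid in self.subtree(r):
                if nid in seen:
                    raise InputError(f"trees are not disjoint at {nid!r}")
                seen.add(nid)
        if seen != set(self.nodes):
            raise InputError("forest contains nodes unreachable from any root")


@dataclass(frozen=True)
class FlipEdge:
    """One interaction gain-or-loss event between two forest nodes.

    ``orientation`` is :data:`UNDIRECTED` for undirected histories, and one of
    :data:`FORWARD` (a -> b), :data:`REVERSE` (b -> a) or :data:`BOTH` for
    directed histories (``BOTH`` counts as two events).  ``t`` is an optional
    event time.
    """

    a: str
    b: str
    orientation: str = UNDIRECTED
    t: Optional[float] = None

    def pair(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)

    @property
    def n_events(self) -> int:
        return 2 if self.orientation == BOTH else 1


@dataclass
class NetworkHistory:
    """A duplication forest together with a set of flip edges."""

    forest: DuplicationForest
    flips: list[FlipEdge] = field(default_factory=list)
    directed: bool = False
    selfloops: bool = False

    def check_flips(self) -> None:
        for f in self.flips:
            if f.a not in self.forest or f.b not in self.forest:
                raise InputError(f"flip endpoint not in forest: {f}")
            if f.a == f.b and not self.selfloops:
                raise ModelError(f"self-flip {f} outside the self-loop variant")
            if self.directed and f.orientation == UNDIRECTED:
                raise ModelError(f"undirected flip {f} in a directed history")
            if not self.directed and f.orientation != UNDIRECTED:
                raise ModelError(f"oriented flip {f} in an undirected history")


class InteractionGraph:
    """An extant (or ancestral) interaction network.

    A thin wrapper over a :mod:`networkx` graph carrying the ``directed`` and
    ``selfloops`` flags and the degree accessors used by the growth models.
    """

    def __init__(self, *, directed: bool = False, selfloops: bool = False) -> None:
        self.directed = directed
        self.selfloops = selfloops
        self.g: nx.Graph = nx.DiGraph() if directed else nx.Graph()

    @classmethod
    def from_edges(cls, nodes: Iterable[str], edges: Iterable[tuple[str, str]],
                   *, directed: bool = False, selfloops: bool = False) -> "InteractionGraph":
        ig = cls(directed=directed, selfloops=selfloops)
        for n in nodes:
            ig.add_node(n)
        for u, v in edges:
            ig.add_edge(u, v)
        return ig

    # -- mutation ---------------------------------------------------------

    def add_node(self, u: str) -> None:
        self.g.add_node(u)

    def remove_node(self, u: str) -> None:
        self.g.remove_node(u)

    def add_edge(self, u: str, v: str) -> None:
        if u == v and not self.selfloops:
            raise InputError(f"self-loop ({u},{v}) in a graph without self-loops")
        if u not in self.g or v not in self.g:
            raise InputError(f"edge ({u},{v}) references an unknown node")
        self.g.add_edge(u, v)

    def remove_edge(self, u: str, v: str) -> None:
        self.g.remove_edge(u, v)

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.g.nodes)

    def edge_set(self) -> set:
        """Edges as ordered tuples (directed) or frozensets (undirected)."""
        if self.directed:
            return {(u, v) for u, v in self.g.edges}
        return {frozenset((u, v)) for u, v in self.g.edges}

    def has_edge(self, u: str, v: str) -> bool:
        return self.g.has_edge(u, v)

    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def k(self, u: str) -> int:
        """Total degree (in + out for directed graphs)."""
        return self.g.degree(u)

    def k_out(self, u: str) -> int:
        return self.g.out_degree(u) if self.directed else self.g.degree(u)

    def k_in(self, u: str) -> int:
        return self.g.in_degree(u) if self.directed else self.g.degree(u)

    def copy(self) -> "InteractionGraph":
        ig = InteractionGraph(directed=self.directed, selfloops=self.selfloops)
        ig.g = self.g.copy()
        return ig

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionGraph):
            return NotImplemented
        return (self.directed == other.directed
                and self.nodes == other.nodes
                and self.edge_set() == other.edge_set())

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"<InteractionGraph {kind} n={len(self.g)} m={self.g.number_of_edges()}>"


# ---------------------------------------------------------------------------
# The parity rule: history -> extant graph.
# ---------------------------------------------------------------------------

def constructs(history: NetworkHistory) -> InteractionGraph:
    """Extant graph implied by a history via the flip-parity rule.

    Nodes are the Present leaves.  An unordered pair ``{u, v}`` interacts iff
    an odd number of flips have one endpoint on the root path of ``u`` and the
    other on the root path of ``v``; the directed rule counts flips oriented
    from u's path to v's path, and self-loops count flips whose endpoints both
    lie on the one path.
    """
    history.check_flips()
    F = history.forest
    out = InteractionGraph(directed=history.directed, selfloops=history.selfloops)
    present = F.present_leaves()
    for u in present:
        out.add_node(u)

    parity: dict[tuple[str, str], int] = {}

    def toggle(pairs: Iterable[tuple[str, str]]) -> None:
        for p in pairs:
            parity[p] = parity.get(p, 0) ^ 1

    desc_cache: dict[str, list[str]] = {}

    def desc(nid: str) -> list[str]:
        if nid not in desc_cache:
            desc_cache[nid] = F.present_leaf_descendants(nid)
        return desc_cache[nid]

    for f in history.flips:
        da, db = desc(f.a), desc(f.b)
        if not history.directed:
            pairs = set()
            for u in da:
                for v in db:
                    if u == v:
                        if history.selfloops:
                            pairs.add((u, u))
                        continue
                    pairs.add((u, v) if u < v else (v, u))
            toggle(pairs)
        else:
            if f.orientation in (FORWARD, BOTH):
                toggle({(u, v) for u in da for v in db
                        if u != v or history.selfloops})
            if f.orientation in (REVERSE, BOTH):
                toggle({(u, v) for u in db for v in da
                        if u != v or history.selfloops})

    for (u, v), p in sorted(parity.items()):
        if p:
            out.add_edge(u, v)
    return out


# ---------------------------------------------------------------------------
# Blocking loops and time assignment.
# ---------------------------------------------------------------------------

def find_blocking_loop(history: NetworkHistory) -> Optional[list[FlipEdge]]:
    """Return one blocking loop (an ordered list of flips) or ``None``.

    Detection runs a DFS in which tree edges are traversed away from the root
    and flips in either direction: each flip yields the two oriented pairs
    ``(u, v)`` and ``(v, u)``, and an oriented flip ``(u', v')`` can follow
    ``(u, v)`` whenever ``u'`` is a proper ancestor of ``v``.  Any cycle of
    oriented flips is a blocking loop; acyclic flip sets are valid.
    """
    F = history.forest
    flips = sorted(history.flips, key=lambda f: (f.a, f.b, f.orientation))
    if not flips:
        return None
    intervals = F.euler_intervals()

    def proper_anc(u: str, v: str) -> bool:
        (iu, ou), (iv, _) = intervals[u], intervals[v]
        return iu < iv <= ou

    # Oriented flip endpoints: (flip index, tail u, head v).
    orient: list[tuple[int, str, str]] = []
    for i, f in enumerate(flips):
        orient.append((i, f.a, f.b))
        if f.a != f.b:
            orient.append((i, f.b, f.a))

    n = len(orient)
    succ: list[list[int]] = []
    for (_, _, v) in orient:
        succ.append([j for j, (_, uj, _) in enumerate(orient) if proper_anc(uj, v)])

    # Iterative DFS cycle detection (white/gray/black).
    color = [0] * n
    for start in range(n):
        if color[start]:
            continue
        stack: list[tuple[int, int]] = [(start, 0)]
        path: list[int] = []
        on_path = [False] * n
        while stack:
            node, ptr = stack.pop()
            if ptr == 0:
                color[node] = 1
                path.append(node)
                on_path[node] = True
            advanced = False
            for k in range(ptr, len(succ[node])):
                nxt = succ[node][k]
                if on_path[nxt]:
                    cyc = path[path.index(nxt):]
                    return [flips[orient[j][0]] for j in cyc]
                if color[nxt] == 0:
                    stack.append((node, k + 1))
                    stack.append((nxt, 0))
                    advanced = True
                    break
            if not advanced:
                color[node] = 2
                path.pop()
                on_path[node] = False
    return None


@dataclass
class TimeAssignment:
    """Integer event times satisfying the existence-interval conditions."""

    t_c: dict[str, int]
    t_d: dict[str, float]
    flip_times: dict[FlipEdge, int]
    ok: bool = True


@dataclass
class StallCertificate:
    """Nodes whose duplication time could never be fixed; witnesses a blocking loop."""

    stalled: frozenset
    ok: bool = False


def assign_times(history: NetworkHistory):
    """Constructively assign times to a history, or certify that none exist.

    Runs the deferred depth-first search over tree edges: every root is
    created at time 0; a node may fix its duplication time only once all its
    flip partners have creation times (each flip occurs at the later of its
    endpoints' creation times, and a duplication happens one tick after the
    last adjacent flip); nodes that cannot proceed wait in a deferred set and
    are retried in rounds.  A round with no progress certifies a blocking
    loop; otherwise the returned times satisfy the validity conditions.
    """
    history.check_flips()
    F = history.forest
    adj: dict[str, list[str]] = {}
    for f in history.flips:
        adj.setdefault(f.a, []).append(f.b)
        if f.a != f.b:
            adj.setdefault(f.b, []).append(f.a)

    t_c: dict[str, int] = {}
    t_d: dict[str, float] = {}
    deferred: set[str] = set()

    def dfs(start: str) -> None:
        stack = [start]
        while stack:
            u = stack.pop()
            node = F[u]
            partners = adj.get(u, ())
            if any(v not in t_c for v in partners):
                deferred.add(u)
                continue
            deferred.discard(u)
            if node.is_leaf:
                t_d[u] = math.inf
                continue
            latest = max((t_c[v] for v in partners), default=t_c[u])
            t_d[u] = max(latest, t_c[u]) + 1
            for c in (node.left, node.right):
                t_c[c] = int(t_d[u])
                stack.append(c)

    for r in sorted(F.roots):
        t_c[r] = 0
        dfs(r)
    while deferred:
        progress = False
        for u in sorted(deferred):
            if u in deferred and all(v in t_c for v in adj.get(u, ())):
                dfs(u)
                progress = True
        if not progress:
            return StallCertificate(stalled=frozenset(deferred))

    flip_times = {f: max(t_c[f.a], t_c[f.b]) for f in history.flips}
    return TimeAssignment(t_c=t_c, t_d=t_d, flip_times=flip_times)


def check_time_conditions(history: NetworkHistory, ta: TimeAssignment) -> bool:
    """First-principles check of the two validity conditions on a time assignment."""
    F = history.forest
    for node in F.nodes.values():
        if not (ta.t_c[node.id] < ta.t_d[node.id]):
            return False
        if not node.is_leaf:
            for c in (node.left, node.right):
                if ta.t_c[c] != ta.t_d[node.id]:
                    return False
    for f in history.flips:
        t = ta.flip_times[f]
        for x in (f.a, f.b):
            if not (ta.t_c[x] <= t < ta.t_d[x]):
                return False
    return True


def is_valid(history: NetworkHistory) -> bool:
    """True iff the history admits a consistent timing (no blocking loop)."""
    return find_blocking_loop(history) is None
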