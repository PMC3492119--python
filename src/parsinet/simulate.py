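"""Ground-truthed network-evolution simulators.

Generates evolution instances for benchmarking: a random connected seed
graph is evolved into an ancestral regulatory network ``X``; a speciation
event copies ``X`` into two lineages, each of which evolves further while a
duplication forest (one tree per ancestral gene, i.e. homology group) and a
full event log are maintained.  Growth models:

* **DDM** (degree-dependent): node duplication / node loss / interaction
  gain / interaction loss occur with probabilities ``p_ndup, p_nloss,
  p_egain, p_eloss``; the object of an event is degree-weighted —
  duplication and loss of ``u`` with weight 1/k_u, gain of an ordered
  non-edge (u, v) with weight k_u^o (preferential attachment at the source,
  uniform target), loss of an edge (u, v) with weight 1/k_u^o.
* **DIM** (degree-independent): same events, objects chosen uniformly.
* **Foster**: duplication-centric regulatory growth — a uniformly chosen
  gene duplicates, the copy keeps each incoming regulator with probability
  ``p_inkeep`` and each outgoing target with ``p_outkeep``, and innovates a
  new outgoing edge with probability ``p_innovation``.

After every event, genes that regulate nothing (out-degree 0) are pruned
transitively and marked as Absent leaves.  Simulated ancestors can be
filtered for biological plausibility by their degree distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .core import (FORWARD, DuplicationForest, FlipEdge, InteractionGraph,
                   NetworkHistory)
from .errors import InputError, SimulationRestart

DDM = "DDM"
DIM = "DIM"
FOSTER = "Foster"


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated instance.

    Defaults are the divergence-experiment settings: a connected seed graph
    of 10 genes and 25 interactions, 200 degree-dependent operations to the
    ancestor and 200 per lineage with event probabilities
    (0.35, 0.05, 0.3, 0.3).
    """

    model: str = DDM
    p_ndup: float = 0.35
    p_nloss: float = 0.05
    p_egain: float = 0.30
    p_eloss: float = 0.30
    p_inkeep: float = 0.5
    p_outkeep: float = 0.5
    p_innovation: float = 0.1
    seed_nodes: int = 10
    seed_edges: int = 25
    ops_to_ancestor: int = 200
    ops_per_lineage: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_ndup, self.p_nloss, self.p_egain, self.p_eloss,
                 self.p_inkeep, self.p_outkeep, self.p_innovation)
        if any(p < 0 or p > 1 for p in probs):
            raise InputError("probabilities must lie in [0, 1]")
        if self.model not in (DDM, DIM, FOSTER):
            raise InputError(f"unknown model {self.model!r}")

    def event_probs(self) -> np.ndarray:
        p = np.array([self.p_ndup, self.p_nloss, self.p_egain, self.p_eloss])
        if p.sum() <= 0:
            raise InputError("event probabilities sum to zero")
        return p / p.sum()


@dataclass
class SimulationInstance:
    """Ground truth for one simulated speciation: ancestor ``X``, the two
    extant networks with their duplication forests, and the event logs."""

    X: InteractionGraph
    G1: InteractionGraph
    G2: InteractionGraph
    F1: DuplicationForest
    F2: DuplicationForest
    events1: list = field(default_factory=list)
    events2: list = field(default_factory=list)
    params: Optional[SimulationParams] = None

    def true_history(self, lineage: int) -> NetworkHistory:
        """The lineage's logged events as a network history: one root-level
        flip per ancestral interaction plus one flip per gain/loss event.
        Constructing it must reproduce the extant network."""
        forest = self.F1 if lineage == 1 else self.F2
        events = self.events1 if lineage == 1 else self.events2
        flips = [FlipEdge(u, v, FORWARD, t=-1.0) for u, v in sorted(self.X.g.edges)]
        for ev in events:
            if ev["op"] in ("egain", "eloss"):
                u, v = ev["obj"]
                flips.append(FlipEdge(u, v, FORWARD, t=float(ev["t"])))
        return NetworkHistory(forest, flips, directed=True, selfloops=False)


# ---------------------------------------------------------------------------
# Seed graph
# ---------------------------------------------------------------------------

def random_seed_graph(n: int, m: int, rng: np.random.Generator) -> InteractionGraph:
    """Random weakly connected simple digraph with ``n`` nodes and ``m`` arcs
    (no self-loops, no parallel arcs; anti-parallel arcs allowed)."""
    if n < 1 or m < n - 1 or m > n * (n - 1):
        raise InputError(f"infeasible seed-graph size ({n}, {m})")
    names = [f"s{i}" for i in range(n)]
    G = InteractionGraph(directed=True)
    for name in names:
        G.add_node(name)
    # random spanning structure for weak connectivity
    for i in range(1, n):
        j = int(rng.integers(i))
        u, v = names[i], names[j]
        if rng.random() < 0.5:
            u, v = v, u
        G.add_edge(u, v)
    while G.n_edges() < m:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        u, v = names[int(i)], names[int(j)]
        if not G.has_edge(u, v):
            G.add_edge(u, v)
    return G


# ---------------------------------------------------------------------------
# Event sampling and application
# ---------------------------------------------------------------------------

def sample_event(G: InteractionGraph, params: SimulationParams,
                 rng: np.random.Generator):
    """Draw one modification ``(op, object)`` from the mixture
    P(modification) = P_operation · P(object | operation), renormalized over
    the operations that are feasible in the current graph."""
    nodes = sorted(G.nodes)
    if not nodes:
        raise SimulationRestart("graph is empty")
    edges = sorted(G.g.edges)
    n = len(nodes)
    nonedge_counts = np.array(
        [n - 1 - sum(1 for w in G.g.successors(u) if w != u) for u in nodes],
        dtype=float)
    p_op = params.event_probs()
    feasible = np.array([True,
                         True,
                         nonedge_counts.sum() > 0,
                         len(edges) > 0])
    w_op = np.where(feasible, p_op, 0.0)
    if w_op.sum() <= 0:
        raise SimulationRestart("no feasible operation")
    op = ["ndup", "nloss", "egain", "eloss"][
        int(rng.choice(4, p=w_op / w_op.sum()))]
    degree_weighted = params.model == DDM

    if op in ("ndup", "nloss"):
        if degree_weighted:
            w = np.array([1.0 / G.k(u) for u in nodes])
        else:
            w = np.ones(len(nodes))
        u = nodes[int(rng.choice(len(nodes), p=w / w.sum()))]
        return op, u
    if op == "egain":
        if degree_weighted:
            w = np.array([G.k_out(u) for u in nodes], dtype=float) * nonedge_counts
        else:
            w = nonedge_counts.copy()
        u = nodes[int(rng.choice(len(nodes), p=w / w.sum()))]
        targets = [v for v in nodes if v != u and not G.has_edge(u, v)]
        v = targets[int(rng.integers(len(targets)))]
        return op, (u, v)
    # eloss: weight 1/k_u^o per edge (u, v), which makes the source uniform
    # over nodes with out-neighbours and the target uniform among them
    if not degree_weighted:
        return op, edges[int(rng.integers(len(edges)))]
    srcs = sorted({u for u, _ in edges})
    u = srcs[int(rng.integers(len(srcs)))]
    outs = sorted(G.g.successors(u))
    v = outs[int(rng.integers(len(outs)))]
    return op, (u, v)


def _prune(G: InteractionGraph, forest: DuplicationForest, log: list,
           t: int) -> None:
    while True:
        dead = sorted(u for u in G.nodes if G.k_out(u) == 0)
        if not dead:
            break
        for u in dead:
            G.remove_node(u)
            forest.set_absent(u)
            log.append({"t": t, "op": "prune", "obj": u})
    if not G.nodes:
        raise SimulationRestart("network died out")


def _duplicate(G: InteractionGraph, forest: DuplicationForest, u: str
               ) -> tuple[str, str]:
    """Replace gene ``u`` by two copies, both inheriting all interactions."""
    c1, c2 = f"{u}.0", f"{u}.1"
    forest.split_leaf(u, c1, c2)
    preds = [w for w in G.g.predecessors(u) if w != u]
    succs = [w for w in G.g.successors(u) if w != u]
    G.remove_node(u)
    G.add_node(c1)
    G.add_node(c2)
    for c in (c1, c2):
        for w in preds:
            G.add_edge(w, c)
        for w in succs:
            G.add_edge(c, w)
    return c1, c2


def evolve(G: InteractionGraph, forest: DuplicationForest,
           params: SimulationParams, n_ops: int, rng: np.random.Generator,
           log: Optional[list] = None, t0: int = 0) -> list:
    """Apply ``n_ops`` sampled DDM/DIM events in place; returns the event log.

    Raises :class:`SimulationRestart` if the network dies out.
    """
    if log is None:
        log = []
    for t in range(t0, t0 + n_ops):
        op, obj = sample_event(G, params, rng)
        if op == "ndup":
            c1, c2 = _duplicate(G, forest, obj)
            log.append({"t": t, "op": "ndup", "obj": obj, "children": (c1, c2)})
        elif op == "nloss":
            G.remove_node(obj)
            forest.set_absent(obj)
            log.append({"t": t, "op": "nloss", "obj": obj})
        elif op == "egain":
            G.add_edge(*obj)
            log.append({"t": t, "op": "egain", "obj": obj})
        else:
            G.remove_edge(*obj)
            log.append({"t": t, "op": "eloss", "obj": obj})
        _prune(G, forest, log, t)
    return log


def foster_evolve(G: InteractionGraph, forest: DuplicationForest,
                  params: SimulationParams, n_ops: int,
                  rng: np.random.Generator, log: Optional[list] = None,
                  t0: int = 0) -> list:
    """Duplication-centric regulatory growth with per-edge retention."""
    if log is None:
        log = []
    for t in range(t0, t0 + n_ops):
        nodes = sorted(G.nodes)
        if not nodes:
            raise SimulationRestart("graph is empty")
        u = nodes[int(rng.integers(len(nodes)))]
        c1, c2 = f"{u}.0", f"{u}.1"
        forest.split_leaf(u, c1, c2)
        preds = [w for w in G.g.predecessors(u) if w != u]
        succs = [w for w in G.g.successors(u) if w != u]
        G.remove_node(u)
        G.add_node(c1)
        G.add_node(c2)
        for w in preds:          # c1 is the original, c2 the divergent copy
            G.add_edge(w, c1)
        for w in succs:
            G.add_edge(c1, w)
        kept_in = [w for w in preds if rng.random() < params.p_inkeep]
        kept_out = [w for w in succs if rng.random() < params.p_outkeep]
        for w in kept_in:
            G.add_edge(w, c2)
        for w in kept_out:
            G.add_edge(c2, w)
        log.append({"t": t, "op": "ndup", "obj": u, "children": (c1, c2)})
        if rng.random() < params.p_innovation:
            targets = [v for v in sorted(G.nodes)
                       if v != c2 and not G.has_edge(c2, v)]
            if targets:
                v = targets[int(rng.integers(len(targets)))]
                G.add_edge(c2, v)
                log.append({"t": t, "op": "egain", "obj": (c2, v)})
        _prune(G, forest, log, t)
    return log


# ---------------------------------------------------------------------------
# Full instances
# ---------------------------------------------------------------------------

def _fresh_forest(X: InteractionGraph) -> DuplicationForest:
    F = DuplicationForest()
    for g in sorted(X.nodes):
        F.add_singleton(g, group=g)
    return F


def _evolve_model(G, F, params, n_ops, rng, log=None):
    fn = foster_evolve if params.model == FOSTER else evolve
    return fn(G, F, params, n_ops, rng, log)


def simulate_ancestor(params: SimulationParams, rng: np.random.Generator
                      ) -> InteractionGraph:
    """Seed graph evolved by ``ops_to_ancestor`` events; nodes are relabelled
    g0, g1, ... to serve as homology-group ids."""
    G = random_seed_graph(params.seed_nodes, params.seed_edges, rng)
    F = _fresh_forest(G)  # throwaway; pre-speciation history is not scored
    _evolve_model(G, F, params, params.ops_to_ancestor, rng)
    mapping = {u: f"g{i}" for i, u in enumerate(sorted(G.nodes))}
    X = InteractionGraph(directed=True)
    for u in mapping.values():
        X.add_node(u)
    for u, v in G.g.edges:
        X.add_edge(mapping[u], mapping[v])
    return X


def generate_ancestor(params: SimulationParams, *, accepted_only: bool = False,
                      max_restarts: int = 10000) -> InteractionGraph:
    """Simulate ancestral networks until one survives (and, optionally,
    passes the plausibility filter)."""
    rng = np.random.default_rng(params.rng_seed)
    for _ in range(max_restarts):
        try:
            X = simulate_ancestor(params, rng)
        except SimulationRestart:
            continue
        if not accepted_only or accept_instance(X):
            return X
    raise SimulationRestart(f"no viable ancestor in {max_restarts} attempts")


def generate_instance(params: SimulationParams, *, accepted_only: bool = False,
                      max_restarts: int = 10000) -> SimulationInstance:
    """Seed -> ancestor -> speciation -> two independently evolved lineages.

    ``accepted_only`` repeats ancestor generation until the degree-distribution
    plausibility filter (:func:`accept_instance`) passes.  Any lineage that
    dies out restarts the whole instance with fresh randomness.
    """
    rng = np.random.default_rng(params.rng_seed)
    for _ in range(max_restarts):
        try:
            X = simulate_ancestor(params, rng)
            if accepted_only and not accept_instance(X):
                continue
            G1, F1 = X.copy(), _fresh_forest(X)
            G2, F2 = X.copy(), _fresh_forest(X)
            ev1 = _evolve_model(G1, F1, params, params.ops_per_lineage, rng)
            ev2 = _evolve_model(G2, F2, params, params.ops_per_lineage, rng)
        except SimulationRestart:
            continue
        return SimulationInstance(X=X, G1=G1, G2=G2, F1=F1, F2=F2,
                                  events1=ev1, events2=ev2, params=params)
    raise SimulationRestart(f"no viable instance in {max_restarts} attempts")


# ---------------------------------------------------------------------------
# Plausibility filter
# ---------------------------------------------------------------------------

def exponential_rate_mle(sample) -> float:
    """MLE rate of an exponential distribution (1 / sample mean)."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0 or x.mean() <= 0:
        return np.inf
    return 1.0 / x.mean()


def powerlaw_exponent_mle(sample, x_min: int = 1) -> float:
    """MLE exponent of a discrete power law (zeta distribution, x >= x_min)."""
    x = np.asarray(sample, dtype=float)
    x = x[x >= x_min]
    if x.size == 0:
        return np.inf
    slogx = np.log(x / 1.0).sum()

    def nll(a: float) -> float:
        z = zeta(a, x_min)
        if not np.isfinite(z) or z <= 0:
            return np.inf
        return x.size * np.log(z) + a * slogx

    res = minimize_scalar(nll, bounds=(1.05, 8.0), method="bounded")
    return float(res.x)


def accept_instance(X: InteractionGraph) -> bool:
    """Plausibility filter on a simulated ancestor: accept if the in-degrees
    fit an exponential law with rate in [1.0, 1.2] or the out-degrees fit a
    discrete power law with exponent in [1.8, 2.2]."""
    nodes = sorted(X.nodes)
    if len(nodes) < 3:
        return False
    in_degs = [X.k_in(u) for u in nodes]
    out_degs = [X.k_out(u) for u in nodes]
    if len(set(in_degs)) > 1:
        rate = exponential_rate_mle(in_degs)
        if 1.0 <= rate <= 1.2:
            return True
    if len(set(out_degs)) > 1:
        gamma = powerlaw_exponent_mle(out_degs)
        if 1.8 <= gamma <= 2.2:
            return True
    return False
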