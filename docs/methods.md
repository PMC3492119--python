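# Methods

This note documents the models and algorithms implemented in `parsinet`,
the assumptions behind them, the numerical and design choices that were
genuinely open, and what the simulation benchmarks do and do not show.

## The history model

Gene-family evolution is encoded as a *duplication forest*: one rooted
binary tree per homology group, internal nodes being duplication events
(after which the parent gene conceptually ceases to exist, replaced by its
two children) and leaves being extant (`Present`) or lost (`Absent`)
genes.  Interaction evolution is encoded by *flip edges* between forest
nodes: one flip between u and v toggles the interaction state of every
extant pair (x, y) with u on x's root path and v on y's root path.  The
extant network is therefore a parity readout of the flips — an odd number
of flips between two root paths means the pair interacts.  The model
covers gene duplication, gene loss, interaction gain and interaction loss;
de novo gene birth is outside the model.

Not every flip set is realizable in time.  A flip between u and v can only
happen while both genes exist, and children postdate their parent's
duplication.  These constraints fail exactly when the flips contain a
*blocking loop*: flips {u_i, v_i}, i = 0..k−1, with u_{i+1 mod k} a proper
ancestor of v_i ("proper" is forced: a chain through u = v admits a
degenerate timing).  Two algorithms operationalize this equivalence and
are tested against each other:

* **Loop detection.** Each flip is considered in both orientations; an
  oriented flip (u', v') may follow (u, v) when u' properly dominates v.
  Any directed cycle in this successor relation is a blocking loop; the
  detector (`find_blocking_loop`) runs an iterative DFS with a fixed
  node ordering, so its output is deterministic.  A cycle that uses one
  flip in both orientations still contradicts any timing (both uses share
  the one flip time), so cycle-freeness is exactly validity; the test
  suite checks agreement with a verbatim enumeration of the set-based
  definition on thousands of random histories.
* **Time assignment.** `assign_times` constructs integer times: roots are
  created at 0, a node's duplication happens one tick after the last flip
  it participates in, each flip happens at the later of its endpoints'
  creation times, and nodes whose flip partners are not yet created wait
  in a deferred set that is retried in rounds.  A round without progress
  returns the deferred set as a stall certificate.  On every random
  history tested, success is equivalent to loop-freeness, and returned
  times satisfy all interval conditions.

## Minimum-cost reconstruction

Given a forest and an extant network, the reconstruction problem asks for
a valid history with minimum total event cost.  The dynamic program
(`parsimony` module) solves the relaxation that forbids only 1- and
2-blocking loops: `S(u, f)` scores a subtree, `A(u, v, f)` scores the
interactions crossing between two disjoint subtrees, and each `A` step
either descends into children on one side or first places a flip between
the current pair (flipping the crossing parity) and then descends.  Only
two parity states per pair arise (plain/complemented; two independent
bits for directed networks), giving O(n²) states filled bottom-up over
subtree-disjoint node pairs by numba-compiled kernels; backtracking
recovers a witness flip set with deterministic tie-breaking in a fixed
option order.

Key conventions, chosen where the recurrences alone do not dictate them:

* **Add vs. loss.** A flip placed at even parity creates an interaction
  (cost `c_add`); at odd parity it deletes one (`c_loss`).  Ancestral
  root pairs start interaction-free, and parity counts the flips already
  placed above the pair, so parity is exactly the creation/deletion
  alternation.
* **Absent subtrees.** Pairs whose extant descendants include no Present
  leaf cost 0 at every parity: lost lineages impose no observable
  constraint, and any other convention would force events onto
  unobservable branches.
* **Directed networks.** A pair may carry a flip u→v, v→u, both (two
  events), or none; each direction has its own parity bit and cost.
* **Self-loops.** A self-flip at u toggles every interaction, self-loops
  included, among u's descendants; the leaf base case charges
  `f(leaf,leaf)·c(parity)`.  The directed and self-loop variants are not
  combined.
* **Branch lengths.** When the forest carries branch lengths, each node
  has a real existence interval [t_c, t_d); a flip between nodes whose
  intervals are disjoint additionally costs α·δ, δ being the gap between
  the intervals.  α = 0 (default) ignores branch lengths entirely; α = ∞
  turns them into hard constraints.  The penalty is charged per event
  (twice for a directed "both" flip).
* **Numerics.** Costs are floats; backtracking matches DP values within
  1e-9 relative tolerance, which is exact for the integer-valued
  unit-cost setting.

The DP total (Σ_r S(r) over roots plus Σ_{r<q} A(r, q) over root pairs) is
a certified lower bound on the valid optimum.  If the backtracked flip set
contains a blocking loop of length ≥ 3, the loop breaker picks one flip of
the first detected loop uniformly at random (seeded), forbids that node
pair's flip options, and re-runs the DP; the forbidden set grows strictly,
and flips at leaf pairs can never participate in loops, so termination is
guaranteed.  The final cost is reported together with the lower bound; in
the simulation suite loops arise in only a few percent of reconstructions
and breaking them almost never increases the cost.

## Ancestor inference

After speciation the two lineages evolve independently, so ancestral
interactions between homology groups r and q are decided directly from
the two forests' first-pass DP tables: create {r, q} iff
`c_add + A_F1(r,q,odd) + A_F2(r,q,odd) < A_F1(r,q,even) + A_F2(r,q,even)`.
Ties yield no edge (the inequality is strict), a group missing from one
species contributes zero to both sides, the weighted form replaces the
leading 1 by `c_add` (the ancestral edge's own creation), and the directed
rule is applied per direction with the corresponding parity bit.  No loop
breaking is applied before reading the tables.  Ancestral self-loops
(via the self-flip recurrence at the roots) are an extension beyond the
pairwise rule and are disabled by default.

## Simulators

`simulate` generates ground-truthed instances: a random weakly connected
directed seed graph (10 genes, 25 interactions by default) is evolved by
`ops_to_ancestor = 200` events into the ancestor X; a speciation event
copies X; each lineage then evolves independently for `ops_per_lineage`
events while its duplication forest (one tree per ancestral gene) and a
complete event log are maintained.

* **DDM** (degree-dependent): events ndup/nloss/egain/eloss with
  probabilities (0.35, 0.05, 0.30, 0.30) by default; object choice is
  degree-weighted — duplication and loss pick u ∝ 1/k_u, edge gain picks
  an ordered non-adjacent pair ∝ k_u^o (preferential attachment at the
  source), edge loss picks an edge ∝ 1/k_u^o.  The event mixture is
  renormalized over operations feasible in the current graph.
* **DIM**: identical events, objects uniform.  On a regular graph the two
  models coincide, which the tests check distributionally.
* **Foster**: duplication-only regulatory growth; the copy keeps each
  incoming edge with `p_inkeep`, each outgoing edge with `p_outkeep`, and
  innovates a new outgoing edge with `p_innovation`.  No values are
  canonical for these retention probabilities; the defaults (0.5, 0.5,
  0.1) sit in the regime where copies usually survive yet diverge, and
  sweeps expose them as configuration.

Duplication copies **all** incident interactions to both children (a copy
with no outgoing regulation would be pruned immediately); divergence
between the copies is produced by subsequent edge events, not by the
duplication itself.  After every event, genes with out-degree 0 are
removed transitively (a regulator whose every target disappeared stops
being part of the regulatory network) and marked Absent; "operations" are
the sampled events, with pruning removals not counted.  A lineage that
dies out restarts the whole instance with fresh randomness.  Event-level
gains and losses are logged as flips at the genes alive at that moment,
and the logged history provably reconstructs the extant network — an
end-to-end consistency check between the simulator and the parity model
that the tests exercise.

Simulated ancestors can be filtered for biological plausibility: accept X
if its in-degrees fit an exponential law with ML rate in [1.0, 1.2]
(rate = 1/mean) or its out-degrees fit a discrete power law with ML
exponent in [1.8, 2.2] (zeta likelihood, x_min = 1); constant degree
sequences fit neither.  In practice the exponential branch essentially
never fires on these graphs (they are too dense) and the power-law branch
accepts a small minority, biased toward smaller, sparser, more fragile
networks.  The benchmark experiments therefore apply the filter only
where the protocol calls for it (the ancestor-size calibration); the
divergence and loop-breaking experiments run on unfiltered ancestors,
whose mean size (~57 genes after 200 operations) matches the intended
scale of ~55.

## Evaluation

Inferred ancestors are scored against the true X at the homology-group
level: precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean.
An empty prediction reports precision 1 (with a warning) so that sweeps
stay total, F1 then collapsing through recall.  The `excluding-lost`
variant removes, from both truth and prediction, every interaction
incident to a group with no Present descendant in either lineage — such
interactions are unrecoverable in principle, and excluding them can only
raise recall.  Sweep drivers report medians and quartiles over replicates
(divergence sweep) or per-grid-point summaries including loop-breaking
statistics (parameter sweep).

## Benchmark scales and what they show

The acceptance script and the heavyweight tests use: a 5-point DDM
probability grid × 20 instances × 2 lineages (200 reconstructions,
200/200-operation protocol) for loop-breaking optimality; 100 replicates
of the 300-operation divergence experiment for ancestor-recovery F1; and
100 accepted ancestors for the size calibration.  These sizes keep a full
run in the minutes range on one CPU while leaving medians stable to a few
hundredths.

The simulations validate the method under its own generative assumptions:
binary duplication histories known without error, independent lineages, no
horizontal transfer, no de novo gene birth, and interaction noise absent.
Passing them shows the reconstruction machinery is correct and
near-optimal at realistic scales; it does not show robustness to
misspecified gene trees or noisy interaction data.  Real applications
(e.g. ancestral bZIP interaction networks from sequence-predicted
interactions) additionally require externally supplied forests and
networks, for which the CLI accepts weighted cost ratios such as 11.4:1
and α ∈ {0, ∞}.

## Known limitations

* Whether the full minimum-valid-history problem is NP-hard is open; the
  package provides a lower-bound certificate rather than exact optima
  when loops must be broken.
* The ancestor rule treats exactly two species; deeper species trees
  would require recursing the construction.
* The DP's exclusion of 2-blocking loops between non-sibling pairs is
  verified empirically (every backtracked solution is checked), not by a
  formal proof in this codebase.
* Ancestral homodimer inference has no counterpart in the pairwise rule's
  derivation and is therefore opt-in.
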