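"""Simulate network evolution and recover the common ancestor.

Grows a random seed network into an ancestor X under the degree-dependent
model, lets two lineages diverge independently, then infers the ancestral
network from the extant networks and duplication forests alone and scores
it against the ground truth.
"""

from parsinet import generate_instance, infer_ancestor, precision_recall_f1, \
    f1_excluding_lost
from parsinet.simulate import SimulationParams

params = SimulationParams(ops_per_lineage=150, rng_seed=42)
inst = generate_instance(params)
print(f"ancestor X: {len(inst.X.nodes)} genes, {inst.X.n_edges()} interactions")
print(f"extant G1:  {len(inst.G1.nodes)} genes, {inst.G1.n_edges()} interactions")
print(f"extant G2:  {len(inst.G2.nodes)} genes, {inst.G2.n_edges()} interactions")

Xhat = infer_ancestor(inst.F1, inst.F2, inst.G1, inst.G2)
p, r, f1 = precision_recall_f1(Xhat, inst.X)
pe, re_, f1e = f1_excluding_lost(Xhat, inst.X, inst.F1, inst.F2)

print(f"inferred ancestor: {Xhat.n_edges()} interactions")
print(f"precision {p:.3f}  recall {r:.3f}  F1 {f1:.3f}")
print(f"excluding homology groups lost in both lineages: F1 {f1e:.3f}")

# Precision is typically near 1: almost every inferred ancestral interaction
# is real.  Recall is limited by gene loss — interactions whose partners
# left no descendants cannot be recovered, which the second score excludes.
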