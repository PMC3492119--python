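"""Scoring of inferred ancestral networks and the simulation experiments.

Comparison is at the homology-group level: the inferred ancestor and the
ground-truth ancestor are graphs over the same group ids, and precision /
recall / F1 are computed on their edge sets.  Interactions incident to
groups whose descendants were lost in *both* lineages are unrecoverable in
principle; the ``excluding-lost`` variant drops them from the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ancestor import infer_ancestor
from .core import DuplicationForest, InteractionGraph
from .errors import InputError
from .loopbreak import reconstruct_valid_history
from .parsimony import CostModel
from .simulate import SimulationInstance, SimulationParams, generate_instance


def precision_recall_f1(inferred: InteractionGraph, truth: InteractionGraph
                        ) -> tuple[float, float, float]:
    """Edge-level precision, recall and F1 (harmonic mean).

    If nothing is predicted, precision is reported as 1 (with a warning) and
    F1 collapses to 0 through the recall term when the truth is nonempty.
    """
    if inferred.nodes != truth.nodes:
        raise InputError("inferred and true ancestors use different id spaces")
    if inferred.directed != truth.directed:
        raise InputError("directedness mismatch between inferred and truth")
    return _prf(inferred.edge_set(), truth.edge_set())


def _prf(pred: set, true: set) -> tuple[float, float, float]:
    tp = len(pred & true)
    if pred:
        p = tp / len(pred)
    else:
        warnings.warn("no predicted edges; precision reported as 1",
                      stacklevel=3)
        p = 1.0
    r = tp / len(true) if true else 1.0
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


def lost_in_both(F1: DuplicationForest, F2: DuplicationForest) -> set[str]:
    """Homology groups with no Present descendant in either extant network."""
    alive: dict[str, bool] = {}
    for forest in (F1, F2):
        for r in forest.roots:
            g = forest[r].homology_group or r
            alive[g] = alive.get(g, False) or bool(forest.present_leaf_descendants(r))
    return {g for g, ok in alive.items() if not ok}


def f1_excluding_lost(inferred: InteractionGraph, truth: InteractionGraph,
                      F1: DuplicationForest, F2: DuplicationForest
                      ) -> tuple[float, float, float]:
    """Precision/recall/F1 after removing every interaction incident to a
    group lost in both lineages from both the truth and the prediction."""
    if inferred.nodes != truth.nodes:
        raise InputError("inferred and true ancestors use different id spaces")
    lost = lost_in_both(F1, F2)

    def keep(edge) -> bool:
        return not any(x in lost for x in edge)

    pred = {e for e in inferred.edge_set() if keep(e)}
    true = {e for e in truth.edge_set() if keep(e)}
    return _prf(pred, true)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def score_instance(inst: SimulationInstance,
                   costs: Optional[CostModel] = None) -> dict:
    """Reconstruct the ancestor of one instance and score it against truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xhat = infer_ancestor(inst.F1, inst.F2, inst.G1, inst.G2, costs)
        p, r, f1 = precision_recall_f1(Xhat, inst.X)
        pe, re_, f1e = f1_excluding_lost(Xhat, inst.X, inst.F1, inst.F2)
    return {"precision": p, "recall": r, "f1": f1,
            "precision_excl": pe, "recall_excl": re_, "f1_excl": f1e,
            "ancestor_size": len(inst.X.nodes),
            "g1_size": len(inst.G1.nodes), "g2_size": len(inst.G2.nodes)}


def _replicate_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2 ** 31, size=n)]


def divergence_replicates(params: SimulationParams, distance: int,
                          replicates: int, seed: int,
                          costs: Optional[CostModel] = None,
                          accepted_only: bool = False) -> pd.DataFrame:
    """Per-replicate scores at one evolutionary distance (ops per lineage)."""
    rows = []
    for s in _replicate_seeds(seed, replicates):
        p = replace(params, ops_per_lineage=distance, rng_seed=s)
        inst = generate_instance(p, accepted_only=accepted_only)
        rows.append(score_instance(inst, costs))
    return pd.DataFrame(rows)


def run_divergence_sweep(params: SimulationParams, distances: Sequence[int],
                         replicates: int = 100, seed: int = 0,
                         costs: Optional[CostModel] = None) -> pd.DataFrame:
    """Median and quartiles of F1 (plain and excluding lost groups) as a
    function of the number of post-speciation operations per lineage."""
    rows = []
    for d in distances:
        df = divergence_replicates(params, d, replicates, seed, costs)
        rows.append({
            "distance": d,
            "f1_q1": df.f1.quantile(0.25), "f1_median": df.f1.median(),
            "f1_q3": df.f1.quantile(0.75),
            "f1_excl_q1": df.f1_excl.quantile(0.25),
            "f1_excl_median": df.f1_excl.median(),
            "f1_excl_q3": df.f1_excl.quantile(0.75),
            "mean_ancestor_size": df.ancestor_size.mean(),
            "replicates": len(df),
        })
    return pd.DataFrame(rows)


def default_ddm_grid(base: Optional[SimulationParams] = None
                     ) -> list[SimulationParams]:
    """A small grid of DDM event-probability settings around the
    divergence-experiment values, used by the loop-breaking suite."""
    base = base or SimulationParams()
    combos = [
        (0.35, 0.05, 0.30, 0.30),
        (0.25, 0.05, 0.35, 0.35),
        (0.45, 0.05, 0.25, 0.25),
        (0.30, 0.10, 0.30, 0.30),
        (0.40, 0.10, 0.25, 0.25),
    ]
    return [replace(base, p_ndup=a, p_nloss=b, p_egain=c, p_eloss=d)
            for a, b, c, d in combos]


def loop_breaking_records(params_grid: Iterable[SimulationParams],
                          replicates: int, seed: int,
                          costs: Optional[CostModel] = None,
                          accepted_only: bool = False) -> pd.DataFrame:
    """Reconstruct each simulated extant network as a valid history and
    record the greedy solution's excess over the DP lower bound."""
    rows = []
    for gi, params in enumerate(params_grid):
        for s in _replicate_seeds(seed + gi, replicates):
            p = replace(params, rng_seed=s)
            inst = generate_instance(p, accepted_only=accepted_only)
            for lineage, (F, G) in enumerate(((inst.F1, inst.G1),
                                              (inst.F2, inst.G2)), start=1):
                res = reconstruct_valid_history(F, G, costs, rng_seed=s + lineage)
                rows.append({
                    "grid_point": gi, "seed": s, "lineage": lineage,
                    "lower_bound": res.lower_bound, "cost": res.cost,
                    "iterations": res.iterations,
                    "relative_excess": res.relative_excess,
                    "n_forest_nodes": len(F),
                    "n_edges": G.n_edges(),
                })
    return pd.DataFrame(rows)


def run_parameter_sweep(model: str, grid: Sequence[dict], replicates: int = 20,
                        seed: int = 0, base: Optional[SimulationParams] = None,
                        costs: Optional[CostModel] = None) -> pd.DataFrame:
    """Reconstruction accuracy across a grid of growth-model parameters.

    Each grid point is a dict of :class:`SimulationParams` overrides; per
    point, simulate -> filter -> reconstruct -> score, and also record the
    loop-breaking statistics of the per-lineage histories.
    """
    base = base or SimulationParams()
    rows = []
    for gi, point in enumerate(grid):
        params = replace(base, model=model, **point)
        scores, excesses, needed = [], [], 0
        for s in _replicate_seeds(seed + 7919 * gi, replicates):
            p = replace(params, rng_seed=s)
            inst = generate_instance(p, accepted_only=True)
            scores.append(score_instance(inst, costs))
            for lineage, (F, G) in enumerate(((inst.F1, inst.G1),
                                              (inst.F2, inst.G2)), start=1):
                res = reconstruct_valid_history(F, G, costs, rng_seed=s + lineage)
                excesses.append(res.relative_excess)
                needed += res.iterations > 0
        df = pd.DataFrame(scores)
        row = dict(point)
        row.update({
            "model": model,
            "f1_q1": df.f1.quantile(0.25), "f1_median": df.f1.median(),
            "f1_q3": df.f1.quantile(0.75),
            "f1_excl_median": df.f1_excl.median(),
            "precision_median": df.precision.median(),
            "recall_median": df.recall.median(),
            "max_relative_excess": max(excesses) if excesses else 0.0,
            "frac_needing_loop_breaking": needed / max(1, 2 * replicates),
            "replicates": replicates,
        })
        rows.append(row)
    return pd.DataFrame(rows)
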