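"""Regulatory hierarchy layout and level-wise TF metrics.

TFs are placed on levels 2..n_levels (non-TF targets implicitly occupy
level 1) by simulated annealing that maximizes the number of TF-TF edges
pointing from a higher to a lower level; TF->target edges are downward by
construction and invariant under the layout.  Level summaries report TF
counts, collaboration scores (fraction of a TF's targets co-targeted by
other TFs), annotation-set fractions, interaction degrees and tau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substreams
from .containers import grn_tfs


@dataclass
class HierarchyAssignment:
    level_of: dict          # TF -> level in [2, n_levels]
    n_levels: int
    downward_fraction: float
    objective_value: int    # downward TF-TF edge count
    note: str = ""


DEFAULT_SA = {"temp0": 1.0, "cooling": 0.995, "moves": 200_000, "restarts": 5}


def _tf_tf_edges(grn: nx.DiGraph, tfs: set):
    return [(u, v) for u, v in grn.edges if u in tfs and v in tfs]


def assign_levels(grn: nx.DiGraph, n_levels: int = 4,
                  sa_params: dict | None = None, seed: int = 0) -> HierarchyAssignment:
    """Anneal TF level assignments to maximize downward TF-TF edges.

    Levels 2..n_levels are available to TFs (level 1 is the target layer).
    Moves reassign one random TF to a random different level with Metropolis
    acceptance and geometric cooling; the best assignment seen across
    restarts is returned.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    params = dict(DEFAULT_SA)
    if sa_params:
        params.update(sa_params)
    tfs = sorted(grn_tfs(grn), key=str)
    if not tfs:
        raise ValueError("GRN has no TFs")
    tf_index = {t: i for i, t in enumerate(tfs)}
    edges = [(tf_index[u], tf_index[v]) for u, v in _tf_tf_edges(grn, set(tfs))]
    n_tf = len(tfs)
    levels = np.arange(2, n_levels + 1)

    note = ""
    if not edges:
        note = "no TF-TF edges; any assignment is optimal"
        level_of = {t: 2 for t in tfs}
        assignment = HierarchyAssignment(level_of, n_levels, 0.0, 0, note)
        assignment.downward_fraction = downward_fraction(grn, assignment)
        return assignment

    out_nbr = [[] for _ in range(n_tf)]
    in_nbr = [[] for _ in range(n_tf)]
    for u, v in edges:
        out_nbr[u].append(v)
        in_nbr[v].append(u)
    out_nbr = [np.array(a, dtype=int) for a in out_nbr]
    in_nbr = [np.array(a, dtype=int) for a in in_nbr]

    (rng,) = substreams(seed, 1)
    src = np.array([u for u, _ in edges])
    dst = np.array([v for _, v in edges])

    if levels.size == 1:  # n_levels == 2: the single TF layer, nothing to move
        level_of = {t: 2 for t in tfs}
        assignment = HierarchyAssignment(level_of, n_levels, 0.0, 0,
                                         "single TF level; layout is fixed")
        assignment.downward_fraction = downward_fraction(grn, assignment)
        return assignment

    out_nbr_l = [a.tolist() for a in out_nbr]
    in_nbr_l = [a.tolist() for a in in_nbr]
    n_moves = int(params["moves"])
    best_obj = -1
    best_lvl = None
    for _ in range(int(params["restarts"])):
        lvl = rng.choice(levels, size=n_tf)
        obj = int(np.sum(lvl[src] > lvl[dst]))
        cur_best_obj, cur_best_lvl = obj, lvl.copy()
        # pre-drawn randomness for the whole sweep (fast inner loop)
        pick_tf = rng.integers(0, n_tf, size=n_moves).tolist()
        pick_lvl = rng.integers(0, levels.size - 1, size=n_moves).tolist()
        unif = rng.random(size=n_moves).tolist()
        temps = np.maximum(params["temp0"] * params["cooling"] ** np.arange(n_moves),
                           1e-6).tolist()
        lvl_l = [int(x) for x in lvl]
        for m in range(n_moves):
            t = pick_tf[m]
            old = lvl_l[t]
            new = 2 + pick_lvl[m]  # uniform over levels excluding the current
            if new >= old:
                new += 1
            delta = 0
            for v in out_nbr_l[t]:
                delta += (new > lvl_l[v]) - (old > lvl_l[v])
            for u in in_nbr_l[t]:
                delta += (lvl_l[u] > new) - (lvl_l[u] > old)
            if delta >= 0 or unif[m] < math.exp(delta / temps[m]):
                lvl_l[t] = new
                obj += delta
                if obj > cur_best_obj:
                    cur_best_obj, cur_best_lvl = obj, np.array(lvl_l)
        if cur_best_obj > best_obj:
            best_obj, best_lvl = cur_best_obj, cur_best_lvl

    level_of = {t: int(best_lvl[i]) for t, i in tf_index.items()}
    assignment = HierarchyAssignment(level_of, n_levels, 0.0, int(best_obj), note)
    assignment.downward_fraction = downward_fraction(grn, assignment)
    return assignment


def downward_fraction(grn: nx.DiGraph, assignment: HierarchyAssignment) -> float:
    """Fraction of all edges going from a higher to a lower level.

    Non-TF targets sit at level 1; every TF in the GRN must be assigned.
    """
    tfs = grn_tfs(grn)
    missing = tfs - set(assignment.level_of)
    if missing:
        raise ValueError(f"unassigned TF, e.g. {next(iter(sorted(missing, key=str)))!r}")
    if grn.number_of_edges() == 0:
        raise ValueError("GRN has no edges")
    level = lambda n: assignment.level_of.get(n, 1)
    down = sum(1 for u, v in grn.edges if level(u) > level(v))
    return down / grn.number_of_edges()


def collaboration_scores(grn: nx.DiGraph) -> dict:
    """Per TF: (# targets co-targeted by other TFs) / (# targets).

    TFs with no targets are omitted with a warning.
    """
    scores = {}
    skipped = []
    for tf in sorted(grn_tfs(grn), key=str):
        targets = list(grn.successors(tf))
        if not targets:
            skipped.append(tf)
            continue
        co = sum(1 for t in targets
                 if any(other != tf for other in grn.predecessors(t)))
        scores[tf] = co / len(targets)
    if skipped:
        warnings.warn(f"{len(skipped)} TFs with no targets omitted from "
                      f"collaboration scores (e.g. {skipped[0]!r})")
    return scores


def level_summaries(assignment: HierarchyAssignment, grn: nx.DiGraph,
                    annotations: dict | None = None,
                    interaction_net: nx.Graph | None = None,
                    tau_profile=None) -> pd.DataFrame:
    """Per-level table: TF count, mean collaboration score, annotation
    fractions, mean interaction degree and mean tau (where provided).

    Level 1 collects the non-TF targets of the GRN.  Annotation genes
    outside the GRN universe are ignored with a warning.
    """
    tfs = grn_tfs(grn)
    universe = set(grn.nodes)
    members = {lv: set() for lv in range(1, assignment.n_levels + 1)}
    for n in grn.nodes:
        members[assignment.level_of.get(n, 1) if n in tfs else 1].add(n)
    collab = collaboration_scores(grn)

    rows = []
    for lv in sorted(members):
        genes = sorted(members[lv], key=str)
        row = {"level": lv, "n_genes": len(genes),
               "n_tfs": sum(1 for g in genes if g in tfs)}
        cs = [collab[g] for g in genes if g in collab]
        row["mean_collaboration"] = float(np.mean(cs)) if cs else np.nan
        if annotations:
            for name, aset in annotations.items():
                outside = set(aset) - universe
                if outside:
                    warnings.warn(f"annotation set {name!r}: {len(outside)} genes "
                                  "outside the GRN universe ignored")
                inside = set(aset) & universe
                row[f"frac_{name}"] = (sum(1 for g in genes if g in inside) / len(genes)
                                       if genes else np.nan)
        if interaction_net is not None:
            degs = [interaction_net.degree(g) for g in genes if g in interaction_net]
            row["mean_interaction_degree"] = float(np.mean(degs)) if degs else np.nan
        if tau_profile is not None:
            taus = [tau_profile.table.loc[g, "tau"] for g in genes
                    if g in tau_profile.table.index]
            row["mean_tau"] = float(np.mean(taus)) if taus else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")
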