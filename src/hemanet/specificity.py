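"""Cell-type specificity scores and active-subnetwork extraction.

Tau summarizes how concentrated a gene's mean (log) expression is in one
cell type: with per-type means x_i, normalized x̂_i = x_i / max(x),

    tau = sum_i (1 - x̂_i) / (N - 1),

0 for ubiquitous expression and 1 for perfect single-type specificity.
Per-type z/p specificity scores standardize each gene's per-type means.
Active subnetworks are connected gene sets whose aggregated specificity
z-scores are unexpectedly high versus random same-size sets, found by
simulated annealing (the jActiveModules scoring scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substreams
from .containers import ExpressionMatrix

_PMIN = 1e-300
_PMAX = 1.0 - 1e-16


@dataclass
class TauProfile:
    table: pd.DataFrame       # per gene: tau, argmax_type, specific
    type_means: pd.DataFrame  # genes x types mean log expression

    def __getitem__(self, gene):
        return float(self.table.loc[gene, "tau"])


@dataclass
class SubnetworkResult:
    genes: tuple
    score: float            # z_A = sum z_g / sqrt(k)
    corrected_score: float  # (z_A - mu_k) / sigma_k from random same-size sets
    connected: bool = True


def _type_mean_matrix(expr: ExpressionMatrix, type_labels: dict,
                      log_transform: bool) -> pd.DataFrame:
    missing = [c for c in expr.cell_ids if c not in type_labels]
    if missing:
        raise ValueError(f"cells without type label, e.g. {missing[0]!r}")
    types = sorted({type_labels[c] for c in expr.cell_ids}, key=str)
    x = expr.dense()
    if log_transform:
        x = np.log1p(x)
    cols = {}
    for t in types:
        idx = [i for i, c in enumerate(expr.cell_ids) if type_labels[c] == t]
        if not idx:
            raise ValueError(f"type {t!r} has no cells")
        cols[t] = x[:, idx].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(expr.gene_ids, name="gene"))


def tau(expr: ExpressionMatrix, type_labels: dict, log_transform: bool = True,
        threshold: float = 0.8) -> TauProfile:
    """Tau specificity per gene; genes with tau > ``threshold`` are flagged
    specific and assigned to their highest-expressing type.  All-zero genes
    get tau = 0 by convention."""
    xm = _type_mean_matrix(expr, type_labels, log_transform)
    if xm.shape[1] < 2:
        raise ValueError("tau needs at least 2 cell types (N - 1 > 0)")
    x = xm.to_numpy()
    n_types = x.shape[1]
    mx = x.max(axis=1)
    t = np.zeros(x.shape[0])
    ok = mx > 0
    t[ok] = (1.0 - x[ok] / mx[ok, None]).sum(axis=1) / (n_types - 1)
    argmax_type = xm.columns.to_numpy()[np.argmax(x, axis=1)]
    table = pd.DataFrame(
        {"tau": t, "argmax_type": argmax_type, "specific": t > threshold},
        index=xm.index,
    )
    return TauProfile(table, xm)


def type_specificity_z(expr: ExpressionMatrix, type_labels: dict,
                       log_transform: bool = True):
    """Per-gene, per-type specificity z (mean-centered across types, sample
    sd) and one-sided upper-tail normal p.  Returns ``(z, p)`` DataFrames."""
    xm = _type_mean_matrix(expr, type_labels, log_transform)
    if xm.shape[1] < 3:
        raise ValueError("type z-scores need at least 3 cell types")
    x = xm.to_numpy()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[~np.isfinite(z)] = 0.0
    p = stats.norm.sf(z)
    p[z == 0] = np.where(np.broadcast_to(sd == 0, z.shape)[z == 0], 1.0, p[z == 0])
    zdf = pd.DataFrame(z, index=xm.index, columns=xm.columns)
    pdf = pd.DataFrame(p, index=xm.index, columns=xm.columns)
    return zdf, pdf


def _gene_z_from_p(gene_p, genes) -> np.ndarray:
    """Upper-quantile transform z = Phi^-1(1 - p); Stouffer across columns."""
    if isinstance(gene_p, pd.DataFrame):
        pm = gene_p.reindex(genes).fillna(1.0).to_numpy(dtype=float)
    else:
        pm = np.array([[float(gene_p.get(g, 1.0))] for g in genes])
    if np.any(pm <= 0):
        raise ValueError("p-values must be strictly positive")
    pm = np.clip(pm, _PMIN, _PMAX)
    zm = stats.norm.isf(pm)
    return zm.sum(axis=1) / np.sqrt(zm.shape[1])


class _Background:
    """Monte-Carlo mean/sd of z_A over random size-k gene sets (cached)."""

    def __init__(self, z: np.ndarray, rng: np.random.Generator, n_samples: int = 1000):
        self.z = z
        self.rng = rng
        self.n_samples = n_samples
        self._cache: dict[int, tuple[float, float]] = {}

    def __call__(self, k: int) -> tuple[float, float]:
        if k not in self._cache:
            n = self.z.size
            idx = self.rng.integers(0, n, size=(self.n_samples, min(k, n)))
            za = self.z[idx].sum(axis=1) / np.sqrt(k)
            self._cache[k] = (float(za.mean()), float(za.std(ddof=1)))
        return self._cache[k]


def _corrected(score: float, k: int, bg: _Background) -> float:
    mu, sd = bg(k)
    if sd == 0:
        return 0.0
    return (score - mu) / sd


def active_subnetwork(net: nx.Graph, gene_p, n_starts: int = 5,
                      sa_params: dict | None = None, seed: int = 0,
                      n_results: int = 3) -> list[SubnetworkResult]:
    """Search for connected subnetworks with high aggregate specificity.

    ``gene_p`` maps gene -> p-value (dict) or is a genes x conditions
    DataFrame (conditions combined by Stouffer's method).  Scoring:
    z_A = sum(z_g)/sqrt(k), corrected against >= 1000 random size-k sets.
    Simulated annealing toggles one gene per move (add a neighbor of the
    set, or remove a non-articulation member), geometric cooling.
    Returns the best non-overlapping results, highest corrected score first.
    """
    params = {"temp0": 1.0, "cooling": 0.995, "iterations": 100_000,
              "background_samples": 1000}
    if sa_params:
        params.update(sa_params)
    genes = list(net.nodes)
    if not genes:
        raise ValueError("network is empty")
    z = _gene_z_from_p(gene_p, genes)
    zmap = dict(zip(genes, z))
    rng_bg, rng_sa = substreams(seed, 2)
    bg = _Background(z, rng_bg, params["background_samples"])

    results = []
    order = np.argsort(-z)  # bias the first start toward the best gene
    for s in range(n_starts):
        start = genes[int(order[0])] if s == 0 else genes[int(rng_sa.integers(len(genes)))]
        best = _anneal(net, zmap, bg, start, rng_sa, params)
        results.append(best)

    results.sort(key=lambda r: -r.corrected_score)
    chosen, used = [], set()
    for r in results:
        if used.isdisjoint(r.genes):
            chosen.append(r)
            used.update(r.genes)
        if len(chosen) >= n_results:
            break
    return chosen


def _articulation_points(adj: dict, members: set) -> set:
    """Articulation points of the induced subgraph on ``members``
    (iterative Tarjan lowpoint DFS on plain adjacency dicts)."""
    disc, low, arts = {}, {}, set()
    for root in members:
        if root in disc:
            continue
        stack = [(root, None, iter(adj[root] & members))]
        disc[root] = low[root] = len(disc)
        root_children = 0
        while stack:
            u, parent, it = stack[-1]
            advanced = False
            for v in it:
                if v not in disc:
                    disc[v] = low[v] = len(disc)
                    if u == root:
                        root_children += 1
                    stack.append((v, u, iter(adj[v] & members)))
                    advanced = True
                    break
                elif v != parent:
                    low[u] = min(low[u], disc[v])
            if not advanced:
                stack.pop()
                if stack:
                    p = stack[-1][0]
                    low[p] = min(low[p], low[u])
                    if p != root and low[u] >= disc[p]:
                        arts.add(p)
        if root_children > 1:
            arts.add(root)
    return arts


def _anneal(net, zmap, bg, start, rng, params) -> SubnetworkResult:
    adj = {n: set(net.neighbors(n)) - {n} for n in net.nodes}
    current = {start}
    boundary_count: dict = {}  # candidate gene -> #neighbors inside the set

    def _change_membership(gene, add):
        if add:
            current.add(gene)
            boundary_count.pop(gene, None)
        else:
            current.discard(gene)
        for nb in adj[gene]:
            if nb in current:
                continue
            boundary_count[nb] = boundary_count.get(nb, 0) + (1 if add else -1)
            if boundary_count[nb] <= 0:
                del boundary_count[nb]
        if not add and any(nb in current for nb in adj[gene]):
            boundary_count[gene] = sum(nb in current for nb in adj[gene])

    for nb in adj[start]:
        boundary_count[nb] = 1
    sum_z = zmap[start]
    score = _corrected(sum_z / 1.0, 1, bg)
    best = (score, frozenset(current), sum_z)
    temp = params["temp0"]
    cooling = params["cooling"]
    for _ in range(int(params["iterations"])):
        temp = max(temp * cooling, 1e-6)
        can_remove = len(current) > 1
        if boundary_count and (not can_remove or rng.random() < 0.5):
            candidates = sorted(boundary_count)
            gene = candidates[int(rng.integers(len(candidates)))]
            delta, new_k, add = zmap[gene], len(current) + 1, True
        elif can_remove:
            removable = sorted(current - _articulation_points(adj, current))
            if not removable:
                continue
            gene = removable[int(rng.integers(len(removable)))]
            delta, new_k, add = -zmap[gene], len(current) - 1, False
        else:
            break
        new_sum = sum_z + delta
        new_score = _corrected(new_sum / np.sqrt(new_k), new_k, bg)
        if new_score >= score or rng.random() < np.exp((new_score - score) / temp):
            _change_membership(gene, add)
            sum_z, score = new_sum, new_score
            if score > best[0]:
                best = (score, frozenset(current), sum_z)
    k = len(best[1])
    return SubnetworkResult(tuple(sorted(best[1])), float(best[2] / np.sqrt(k)),
                            float(best[0]), True)
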