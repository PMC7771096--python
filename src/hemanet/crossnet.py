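"""Cross-species network comparison.

Homolog restriction, conserved-edge overlap with a resampling null, DiffK
differential connectivity (log(k+10) difference of size-normalized degrees)
with empirical-null normal p-values, tail selection, odds-ratio validation
against reference edge sets, and generic Fisher gene-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substreams
from .containers import CorrelationMatrix
from .synthdata import HomologMap


@dataclass
class OverlapResult:
    observed_overlap: int
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int


def restrict_to_homologs(net_a: nx.Graph, net_b: nx.Graph, homologs: HomologMap):
    """Project both networks onto the shared homolog namespace (species-1 ids).

    Nodes and edges outside the one-to-one map are dropped; the species-2
    network is relabeled to species-1 identifiers.
    """
    to1 = homologs.to_species1()
    keep_a = {a for a, _ in homologs.pairs}
    ra = net_a.subgraph([n for n in net_a.nodes if n in keep_a]).copy()
    rb_nodes = [n for n in net_b.nodes if n in to1]
    rb = nx.relabel_nodes(net_b.subgraph(rb_nodes).copy(), to1)
    return ra, rb


def _sample_pair_indices(rng: np.random.Generator, n_pairs: int, k: int) -> np.ndarray:
    """Uniform sample of k distinct values from range(n_pairs) by rejection."""
    out = np.unique(rng.integers(0, n_pairs, size=int(k * 1.1) + 16))
    while out.size < k:
        extra = rng.integers(0, n_pairs, size=k - out.size + 16)
        out = np.unique(np.concatenate([out, extra]))
    return rng.permutation(out)[:k]


def conserved_overlap_test(net_a: nx.Graph, net_b: nx.Graph, n_perm: int = 1000,
                           seed: int = 0) -> OverlapResult:
    """Observed shared-edge count vs an Erdős null with matched sizes.

    The null resamples both edge sets uniformly among all unordered pairs on
    the union node set, keeping each network's node and edge counts; the
    Monte-Carlo p-value is (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    nodes = sorted(set(net_a.nodes) | set(net_b.nodes), key=str)
    n = len(nodes)
    n_pairs = n * (n - 1) // 2
    ea, eb = net_a.number_of_edges(), net_b.number_of_edges()
    edges_a = {frozenset(e) for e in net_a.edges}
    edges_b = {frozenset(e) for e in net_b.edges}
    observed = len(edges_a & edges_b)

    (rng,) = substreams(seed, 1)
    null = np.empty(n_perm)
    for i in range(n_perm):
        sa = _sample_pair_indices(rng, n_pairs, ea)
        sb = _sample_pair_indices(rng, n_pairs, eb)
        null[i] = np.intersect1d(sa, sb, assume_unique=True).size
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return OverlapResult(observed, float(null.mean()), float(null.std(ddof=1)),
                         float(p), n_perm)


def diffk(net_a: nx.Graph, net_b: nx.Graph, pseudo_count: float = 10.0,
          log_base: float = 10.0, normalize: bool = True) -> pd.DataFrame:
    """Differential connectivity DiffK = log(k1 + c) - log(k2 + c).

    Degrees are first rescaled to a common mean degree (the average of the
    two networks' mean degrees) so the pseudo-count keeps the same meaning
    across networks of different density; disable with ``normalize=False``.
    Genes absent from one network count as degree 0.  Antisymmetric under
    swapping the two networks.
    """
    if net_a.number_of_edges() == 0 or net_b.number_of_edges() == 0:
        raise ValueError("both networks need at least one edge for normalization")
    genes = sorted(set(net_a.nodes) | set(net_b.nodes), key=str)
    ka = np.array([net_a.degree(g) if g in net_a else 0 for g in genes], dtype=float)
    kb = np.array([net_b.degree(g) if g in net_b else 0 for g in genes], dtype=float)
    if normalize:
        target = (ka.mean() + kb.mean()) / 2.0
        ka = ka * (target / ka.mean())
        kb = kb * (target / kb.mean())
    log = np.log10 if log_base == 10 else np.log
    d = log(ka + pseudo_count) - log(kb + pseudo_count)
    return pd.DataFrame(
        {"k_species1": ka, "k_species2": kb, "diffk": d,
         "p_value": np.nan, "fdr": np.nan},
        index=pd.Index(genes, name="gene"),
    )


def diffk_pvalues(table: pd.DataFrame, null_fit: str = "central_quantile") -> pd.DataFrame:
    """Two-sided normal p-values for DiffK against a fitted empirical null.

    ``moments`` fits mean/sd of all values; ``central_quantile`` fits a
    robust normal from the median and scaled IQR (null estimated from the
    uncontaminated center, insensitive to the differential tails).  FDR by
    Benjamini-Hochberg.
    """
    if len(table) < 20:
        raise ValueError("need at least 20 genes to fit the null")
    d = table["diffk"].to_numpy()
    if null_fit == "moments":
        mu, sd = float(np.mean(d)), float(np.std(d, ddof=1))
    elif null_fit == "central_quantile":
        mu = float(np.median(d))
        q1, q3 = np.percentile(d, [25, 75])
        sd = float((q3 - q1) / 1.3489795003921634)  # IQR of the standard normal
    else:
        raise ValueError(f"unknown null_fit {null_fit!r}")
    if sd == 0:
        raise ValueError("DiffK values have zero spread; null undefined")
    p = 2 * stats.norm.sf(np.abs(d - mu) / sd)
    np.clip(p, 0.0, 1.0, out=p)
    out = table.copy()
    out["p_value"] = p
    out["fdr"] = multipletests(p, method="fdr_bh")[1]
    return out


def select_tails(table: pd.DataFrame, top_frac: float = 0.05,
                 bottom_frac: float = 0.05, conserved_frac: float = 0.10):
    """Top/bottom DiffK tails and the low-|DiffK| conserved set.

    Sizes are floor(frac * N); ties broken lexicographically by gene id.
    Returns ``(top, bottom, conserved)`` gene sets.
    """
    if top_frac + bottom_frac + conserved_frac >= 1.0:
        raise ValueError("tail fractions must sum to less than 1")
    n = len(table)
    sizes = {name: int(np.floor(f * n)) for name, f in
             (("top", top_frac), ("bottom", bottom_frac), ("conserved", conserved_frac))}
    for name, s in sizes.items():
        if s < 1:
            raise ValueError(f"{name} fraction selects no genes at N={n}")
    df = table.copy()
    df["_gene"] = df.index.astype(str)
    top = df.sort_values(["diffk", "_gene"], ascending=[False, True]).head(sizes["top"])
    bottom = df.sort_values(["diffk", "_gene"], ascending=[True, True]).head(sizes["bottom"])
    df["_abs"] = df["diffk"].abs()
    conserved = df.sort_values(["_abs", "_gene"], ascending=[True, True]).head(sizes["conserved"])
    return set(top.index), set(bottom.index), set(conserved.index)


def enrichment_odds_ratio(corr: CorrelationMatrix, reference_pairs,
                          cutoffs) -> pd.DataFrame:
    """Odds ratio of reference pairs vs all pairs above correlation cutoffs.

    OR(c) = (fraction of reference pairs with R > c) /
            (fraction of all unordered pairs with R > c).
    NaN where no pair at all exceeds the cutoff.
    """
    genes = {g: i for i, g in enumerate(corr.gene_ids)}
    ref_idx = []
    for a, b in reference_pairs:
        if a not in genes or b not in genes:
            raise ValueError(f"reference pair ({a!r}, {b!r}) outside the gene universe")
        if a != b:
            ref_idx.append((genes[a], genes[b]))
    n = len(corr.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    all_vals = corr.R[iu, ju]
    ref_vals = np.array([corr.R[i, j] for i, j in ref_idx]) if ref_idx else np.empty(0)

    rows = []
    for c in cutoffs:
        n_all = int(np.sum(all_vals > c))
        n_ref = int(np.sum(ref_vals > c)) if ref_vals.size else 0
        if n_all == 0 or ref_vals.size == 0:
            orv = np.nan
        else:
            orv = (n_ref / ref_vals.size) / (n_all / all_vals.size)
        rows.append({"cutoff": float(c), "odds_ratio": orv,
                     "n_reference_above": n_ref, "n_all_above": n_all})
    return pd.DataFrame(rows)


def gene_set_enrichment(query, universe, annotation_sets: dict) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a query set per annotation set."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, members in annotation_sets.items():
        s = set(members) & universe
        a = len(query & s)
        b = len(query) - a
        c = len(s) - a
        d = len(universe) - len(query) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"set": name, "overlap": a, "set_size": len(s),
                     "query_size": len(query), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("set")
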