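"""Co-expression networks from cluster-pair DE z-scores.

Instead of correlating raw (dropout-ridden) expression profiles, every gene
is summarized by one signed z-score per unordered cluster pair — a vector of
X(X-1)/2 differential-expression coordinates for X clusters — and gene-gene
correlations are computed in that z-score space.  The network retains the
top-K correlations (adaptive threshold), by absolute value by default.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy import stats

from .containers import CellClustering, CorrelationMatrix, DEZMatrix, ExpressionMatrix


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    counts = counts[counts > 1]
    return float((counts**3 - counts).sum())


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Wilcoxon rank-sum z per gene (rows), tie-corrected.

    Positive z means higher expression in sample ``a``.
    """
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    data = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(data, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    ties = np.apply_along_axis(_tie_term, 1, data)
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    z = np.zeros(data.shape[0])
    ok = var > 0
    z[ok] = (u[ok] - mu) / np.sqrt(var[ok])
    return z


def _welch_z(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / a.shape[1] + v2 / b.shape[1])
    z = np.zeros_like(m1)
    ok = denom > 0
    z[ok] = (m1[ok] - m2[ok]) / denom[ok]
    return z


def cluster_de_zscores(expr: ExpressionMatrix, clustering: CellClustering,
                       statistic: str = "wilcoxon") -> DEZMatrix:
    """One signed DE z-score per gene per unordered cluster pair.

    For clusters (a, b) with a < b in label order, positive z means higher
    expression in a.  ``statistic`` is ``"wilcoxon"`` (rank-sum with tie
    correction; robust to zero inflation) or ``"welch"`` (t-type z on means).
    Genes with zero variance across both clusters get z = 0.
    """
    if statistic not in ("wilcoxon", "welch"):
        raise ValueError(f"unknown statistic {statistic!r}")
    labels = clustering.labels
    missing = [c for c in expr.cell_ids if c not in labels]
    if missing:
        raise ValueError(f"cells without cluster label, e.g. {missing[0]!r}")
    cluster_ids = clustering.cluster_ids
    cells_of = {cl: [i for i, c in enumerate(expr.cell_ids) if labels[c] == cl]
                for cl in cluster_ids}
    for cl, idx in cells_of.items():
        if len(idx) < 2:
            raise ValueError(f"cluster {cl!r} has fewer than 2 cells")

    x = expr.dense()
    comparisons = [(a, b) for i, a in enumerate(cluster_ids)
                   for b in cluster_ids[i + 1:]]
    z = np.empty((expr.n_genes, len(comparisons)))
    fn = _rank_sum_z if statistic == "wilcoxon" else _welch_z
    for k, (a, b) in enumerate(comparisons):
        z[:, k] = fn(x[:, cells_of[a]], x[:, cells_of[b]])
    return DEZMatrix(z, expr.gene_ids, comparisons)


def zscore_correlation(dez: DEZMatrix, method: str = "pearson") -> CorrelationMatrix:
    """Gene-gene correlation of DE z-score vectors.

    Constant z-vectors (e.g. all-zero DE genes) get correlation 0 to every
    other gene; the diagonal is 1 by convention.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    z = dez.z
    if z.shape[1] < 3:
        raise ValueError("need at least 3 comparison columns for correlation")
    data = stats.rankdata(z, axis=1) if method == "spearman" else z
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.atleast_2d(r)
    r[~np.isfinite(r)] = 0.0  # constant rows -> 0 by convention
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, dez.gene_ids)


def _ranked_pairs(corr: CorrelationMatrix, rank_by: str):
    """Upper-triangle pairs sorted by rank value desc, gene-pair lexicographic."""
    if rank_by not in ("absolute", "signed"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    n = len(corr.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    vals = corr.R[iu, ju]
    key = np.abs(vals) if rank_by == "absolute" else vals
    # lexicographic rank of gene ids for deterministic tie-breaks
    lex = np.argsort(np.argsort(np.asarray(corr.gene_ids, dtype=object)))
    order = np.lexsort((lex[ju], lex[iu], -key))
    return iu[order], ju[order], vals[order], key[order]


def build_coexpression_network(corr: CorrelationMatrix, top_k: int | None = None,
                               threshold: float | None = None,
                               rank_by: str = "absolute",
                               keep_isolated: bool = True) -> nx.Graph:
    """Retain the top-K correlations (or all above a threshold) as edges.

    Exactly one of ``top_k`` / ``threshold`` must be given.  Ties at the
    cutoff are broken by lexicographic gene-pair order so the edge set is
    deterministic.  Edge weights are the signed correlations.
    """
    if (top_k is None) == (threshold is None):
        raise ValueError("give exactly one of top_k or threshold")
    n = len(corr.gene_ids)
    n_pairs = n * (n - 1) // 2
    iu, ju, vals, key = _ranked_pairs(corr, rank_by)
    if threshold is not None:
        top_k = int(np.sum(key >= threshold))
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if top_k > n_pairs:
        raise ValueError(f"top_k={top_k} exceeds the {n_pairs} available pairs")

    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(corr.gene_ids)
    genes = corr.gene_ids
    for i, j, v in zip(iu[:top_k], ju[:top_k], vals[:top_k]):
        g.add_edge(genes[i], genes[j], weight=float(v))
    return g
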