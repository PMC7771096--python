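"""CLR background correction and directed GRN construction.

The context-likelihood-of-relatedness (CLR) step rescales each correlation
R_ij against the distribution of all correlations involving gene i (row) and
gene j (column):

    z_i = (R_ij - mean(row i)) / sd(row i)
    z_j = (R_ij - mean(col j)) / sd(col j)
    z(g_i, g_j) = sqrt(z_i^2 + z_j^2)

Conventions (documented, see docs/methods.md): the diagonal self-correlation
is excluded from the row/column mean and sd; sd is the population standard
deviation; rows with sd = 0 contribute z = 0; the classic CLR clamping of
negative z at 0 before squaring is available via ``clamp_negative``.

Confident pairs (pseudo z >= threshold) involving at least one annotated
transcription factor become directed TF->target edges; TF-TF pairs emit both
orientations.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .containers import CLRMatrix, CorrelationMatrix


def clr_correct(corr: CorrelationMatrix, clamp_negative: bool = False,
                exclude_diagonal: bool = True) -> CLRMatrix:
    """Pseudo z-score matrix from CLR background correction."""
    r = np.asarray(corr.R, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    n = r.shape[0]
    if exclude_diagonal and n > 1:
        off = r.copy()
        np.fill_diagonal(off, np.nan)
        row_mu = np.nanmean(off, axis=1)
        row_sd = np.nanstd(off, axis=1)
        col_mu = np.nanmean(off, axis=0)
        col_sd = np.nanstd(off, axis=0)
    else:
        row_mu, row_sd = r.mean(axis=1), r.std(axis=1)
        col_mu, col_sd = r.mean(axis=0), r.std(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        zi = (r - row_mu[:, None]) / row_sd[:, None]
        zj = (r - col_mu[None, :]) / col_sd[None, :]
    zi[~np.isfinite(zi)] = 0.0  # sd = 0 rows contribute 0
    zj[~np.isfinite(zj)] = 0.0
    if clamp_negative:
        np.maximum(zi, 0.0, out=zi)
        np.maximum(zj, 0.0, out=zj)
    z = np.sqrt(zi**2 + zj**2)
    np.fill_diagonal(z, 0.0)
    return CLRMatrix(z, corr.gene_ids)


def build_grn(clr: CLRMatrix, tf_list, z_threshold: float) -> nx.DiGraph:
    """Directed TF->target network from thresholded CLR confidences.

    Pairs with pseudo z >= ``z_threshold``: (TF, non-TF) gives one edge
    TF->TG; (TF, TF) gives both orientations; pairs with no TF are dropped.
    Nodes without any incident edge are omitted.
    """
    tfs = set(tf_list)
    if not tfs:
        raise ValueError("tf_list is empty; the network would be empty by construction")
    unknown = tfs - set(clr.gene_ids)
    tfs = tfs - unknown
    genes = clr.gene_ids
    z = clr.Z
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = z[iu, ju] >= z_threshold
    g = nx.DiGraph()
    for i, j in zip(iu[keep], ju[keep]):
        gi, gj = genes[i], genes[j]
        conf = float(z[i, j])
        ti, tj = gi in tfs, gj in tfs
        if ti:
            g.add_edge(gi, gj, confidence=conf)
        if tj:
            g.add_edge(gj, gi, confidence=conf)
    for node in g.nodes:
        g.nodes[node]["is_tf"] = node in tfs
    return g
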