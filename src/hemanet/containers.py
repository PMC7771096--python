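"""Shared in-memory containers.

Graphs are plain :mod:`networkx` objects with fixed conventions rather than
wrapper classes, so the whole networkx toolbox stays directly usable:

* co-expression network — ``nx.Graph``; edge attribute ``weight`` holds the
  (signed) correlation.
* regulatory network (GRN) — ``nx.DiGraph``; node attribute ``is_tf`` marks
  transcription factors, edge attribute ``confidence`` holds the CLR pseudo
  z-score.  Every edge source must be a TF.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp


def _as_2d(values):
    if sp.issparse(values):
        return values
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError("expression values must be 2-dimensional")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression values (counts or log values)."""

    values: object  # ndarray or scipy sparse, genes x cells
    gene_ids: list
    cell_ids: list
    species: str = ""

    def __post_init__(self):
        self.values = _as_2d(self.values)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique")
        vmin = self.values.min() if not sp.issparse(self.values) else self.values.data.min(initial=0.0)
        if vmin < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class CellClustering:
    """Cell -> cluster label map; at least two clusters."""

    labels: dict

    def __post_init__(self):
        self.labels = dict(self.labels)
        if self.n_clusters < 2:
            raise ValueError("clustering needs at least 2 clusters")

    @property
    def cluster_ids(self) -> list:
        return sorted(set(self.labels.values()), key=str)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class DEZMatrix:
    """Genes x cluster-pair DE z-scores.

    ``comparisons`` is the ordered list of unordered cluster pairs (a, b)
    with a < b in label order; one column per pair, X(X-1)/2 in total.
    """

    z: np.ndarray
    gene_ids: list
    comparisons: list

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.comparisons = [tuple(c) for c in self.comparisons]
        if self.z.shape != (len(self.gene_ids), len(self.comparisons)):
            raise ValueError("z shape does not match gene_ids x comparisons")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("DE z-scores must be finite")


@dataclass
class CorrelationMatrix:
    """Symmetric N x N gene-gene correlation matrix with unit diagonal."""

    R: np.ndarray
    gene_ids: list

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.gene_ids = list(self.gene_ids)
        n = len(self.gene_ids)
        if self.R.shape != (n, n):
            raise ValueError("R must be square and match gene_ids")


@dataclass
class CLRMatrix:
    """Non-negative pseudo z-scores from CLR background correction."""

    Z: np.ndarray
    gene_ids: list

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        self.gene_ids = list(self.gene_ids)
        n = len(self.gene_ids)
        if self.Z.shape != (n, n):
            raise ValueError("Z must be square and match gene_ids")


def make_grn(edges, tfs, confidences=None) -> nx.DiGraph:
    """Build a GRN DiGraph from (source, target) pairs and a TF set.

    Every edge source must be in ``tfs``; raises otherwise.
    """
    tfs = set(tfs)
    g = nx.DiGraph()
    for i, (u, v) in enumerate(edges):
        if u not in tfs:
            raise ValueError(f"edge source {u!r} is not an annotated TF")
        if u == v:
            raise ValueError("self-loops are not allowed in a GRN")
        conf = 1.0 if confidences is None else float(confidences[i])
        g.add_edge(u, v, confidence=conf)
    for n in g.nodes:
        g.nodes[n]["is_tf"] = n in tfs
    return g


def grn_tfs(grn: nx.DiGraph) -> set:
    return {n for n, d in grn.nodes(data=True) if d.get("is_tf", False)}


def grn_targets(grn: nx.DiGraph) -> set:
    return {n for n, d in grn.nodes(data=True) if not d.get("is_tf", False)}
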