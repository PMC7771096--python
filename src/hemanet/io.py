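"""Readers/writers for the plain-text exchange formats.

Expression matrices travel as a directory with ``matrix.mtx`` (genes x
cells, matrix-market), ``genes.tsv`` and ``cells.tsv`` (cell id, species,
type label).  Networks are edge-list TSVs (a ``#directed`` header line marks
a GRN), gene sets are GMT or one-per-line text, maps and tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import ExpressionMatrix, DEZMatrix, make_grn
from .synthdata import HomologMap


def write_expression(expr: ExpressionMatrix, out_dir, type_labels: dict | None = None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = expr.values if sp.issparse(expr.values) else sp.coo_matrix(expr.values)
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat)
    pd.Series(expr.gene_ids, name="gene_id").to_csv(out / "genes.tsv", sep="\t",
                                                    index=False)
    cells = pd.DataFrame({"cell_id": expr.cell_ids, "species": expr.species})
    if type_labels is not None:
        cells["type"] = [type_labels.get(c, "") for c in expr.cell_ids]
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)


def read_expression(in_dir) -> tuple[ExpressionMatrix, dict]:
    d = Path(in_dir)
    mat = scipy.io.mmread(str(d / "matrix.mtx")).tocsr()
    genes = pd.read_csv(d / "genes.tsv", sep="\t")["gene_id"].tolist()
    cells = pd.read_csv(d / "cells.tsv", sep="\t")
    species = str(cells["species"].iloc[0]) if len(cells) else ""
    types = (dict(zip(cells["cell_id"], cells["type"]))
             if "type" in cells.columns else {})
    return ExpressionMatrix(mat, genes, cells["cell_id"].tolist(), species), types


def write_dez(dez: DEZMatrix, path):
    cols = [f"{a}|{b}" for a, b in dez.comparisons]
    pd.DataFrame(dez.z, index=pd.Index(dez.gene_ids, name="gene"),
                 columns=cols).to_csv(path, sep="\t")


def read_dez(path) -> DEZMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    comparisons = [tuple(c.split("|", 1)) for c in df.columns]
    return DEZMatrix(df.to_numpy(), df.index.tolist(), comparisons)


def write_network(net, path):
    """Edge-list TSV; GRNs (DiGraphs) get a '#directed' header line."""
    path = Path(path)
    with path.open("w") as fh:
        if net.is_directed():
            fh.write("#directed\n")
            fh.write("source\ttarget\tconfidence\n")
            for u, v, d in net.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('confidence', 1.0):.6g}\n")
        else:
            fh.write("gene1\tgene2\tweight\n")
            for u, v, d in net.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.6g}\n")


def read_network(path, tf_list=None):
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.strip() == "#directed":
        df = pd.read_csv(path, sep="\t", skiprows=1)
        tfs = set(tf_list) if tf_list is not None else set(df["source"])
        return make_grn(list(zip(df["source"], df["target"])), tfs,
                        df["confidence"].tolist())
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["gene1"], row["gene2"], weight=float(row["weight"]))
    return g


def write_homolog_map(homologs: HomologMap, path):
    pd.DataFrame(homologs.pairs, columns=["species1", "species2"]).to_csv(
        path, sep="\t", index=False)


def read_homolog_map(path) -> HomologMap:
    df = pd.read_csv(path, sep="\t")
    return HomologMap(list(zip(df.iloc[:, 0], df.iloc[:, 1])))


def read_gene_list(path) -> list:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path):
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError("GMT lines need name, description, >=1 gene")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict, path):
    with Path(path).open("w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([str(name), "na", *sorted(map(str, members))]) + "\n")


def read_cluster_labels(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_pairs(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
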