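"""End-to-end orchestration with manifest logging.

One structured config drives simulate -> DE z-scores -> correlation ->
co-expression networks -> cross-species comparison -> CLR -> GRN(s) ->
topology -> specificity -> hierarchy -> motifs.  Every stage output is
written under the run directory and fingerprinted (sha256) in a JSON
manifest together with the config snapshot and all seeds, so a rerun with
the same config reproduces the digests of every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import __version__, clr, crossnet, hierarchy, io, motifs, specificity, topology, zscore_net
from ._rng import child_seed
from .containers import CellClustering
from .synthdata import SpeciesPairConfig, generate_species_pair

log = logging.getLogger("hemanet.pipeline")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},              # SpeciesPairConfig overrides
    "top_k": 20_000,             # co-expression edges retained per species
    "rank_by": "absolute",
    "grn_thresholds": [3.0, 5.0],
    "overlap_permutations": 100,
    "diffk_null_fit": "central_quantile",
    "hierarchy_levels": 4,
    "hierarchy_sa": {},
    "motif_random": 200,
    "motif_sizes": [3],
    "smallworld_random": 20,
}


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    SpeciesPairConfig(**{**cfg["simulate"], "seed": int(cfg["seed"])})  # validates
    if cfg["top_k"] <= 0:
        raise ValueError("top_k must be positive")
    return cfg


def run_pipeline(config: dict | None = None, out_dir="hemanet_run",
                 dry_run: bool = False) -> dict:
    """Run every stage in dependency order; returns the manifest dict."""
    cfg = validate_config(config or {})
    out = Path(out_dir)
    manifest = {"tool": "hemanet", "version": __version__, "config": cfg,
                "seeds": {}, "stages": {}}
    if dry_run:
        manifest["dry_run"] = True
        return manifest
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def record(stage, name, path):
        manifest["stages"].setdefault(stage, {})[name] = {
            "path": str(path), "sha256": _digest(Path(path))}
        files[name] = Path(path)

    seed = int(cfg["seed"])
    manifest["seeds"]["simulate"] = seed

    log.info("stage simulate")
    sp_cfg = SpeciesPairConfig(**{**cfg["simulate"], "seed": seed})
    expr1, expr2, homologs, truth = generate_species_pair(sp_cfg)
    io.write_expression(expr1, out / "species1", truth.type_of_cell)
    io.write_expression(expr2, out / "species2", truth.type_of_cell)
    io.write_homolog_map(homologs, out / "homologs.tsv")
    record("simulate", "species1", out / "species1" / "matrix.mtx")
    record("simulate", "species2", out / "species2" / "matrix.mtx")
    record("simulate", "homologs", out / "homologs.tsv")

    nets = {}
    corrs = {}
    for name, expr in (("species1", expr1), ("species2", expr2)):
        log.info("stage coexpression (%s)", name)
        labels = {c: truth.type_of_cell[c] for c in expr.cell_ids}
        dez = zscore_net.cluster_de_zscores(expr, CellClustering(labels))
        io.write_dez(dez, out / f"dez_{name}.tsv")
        record("dez", name, out / f"dez_{name}.tsv")
        corr = zscore_net.zscore_correlation(dez)
        corrs[name] = corr
        net = zscore_net.build_coexpression_network(
            corr, top_k=int(cfg["top_k"]), rank_by=cfg["rank_by"])
        io.write_network(net, out / f"coexpr_{name}.tsv")
        record("coexpr", name, out / f"coexpr_{name}.tsv")
        nets[name] = net

    log.info("stage cross-species comparison")
    ra, rb = crossnet.restrict_to_homologs(nets["species1"], nets["species2"], homologs)
    overlap_seed = child_seed(seed, 1)
    manifest["seeds"]["overlap"] = overlap_seed
    ov = crossnet.conserved_overlap_test(ra, rb, n_perm=int(cfg["overlap_permutations"]),
                                         seed=overlap_seed)
    io.write_json(dataclasses.asdict(ov), out / "overlap.json")
    record("compare", "overlap", out / "overlap.json")
    dk = crossnet.diffk(ra, rb)
    dk = crossnet.diffk_pvalues(dk, null_fit=cfg["diffk_null_fit"])
    dk.to_csv(out / "diffk.tsv", sep="\t")
    record("compare", "diffk", out / "diffk.tsv")

    log.info("stage topology")
    sw_seed = child_seed(seed, 2)
    manifest["seeds"]["smallworld"] = sw_seed
    topo = {}
    for name, net in nets.items():
        sw = topology.small_world_odds(net, n_random=int(cfg["smallworld_random"]),
                                       seed=sw_seed)
        slope, r2 = topology.degree_distribution_fit(net)
        topo[name] = {**dataclasses.asdict(sw),
                      "density": topology.network_density(net),
                      "degree_fit_slope": slope, "degree_fit_r2": r2}
    io.write_json(topo, out / "topology.json")
    record("topology", "summary", out / "topology.json")

    log.info("stage GRN")
    clr_mat = clr.clr_correct(corrs["species1"])
    tfs = sorted(truth.tf_ids)
    io.write_gene_list(tfs, out / "tfs.txt")
    record("grn", "tfs", out / "tfs.txt")
    grns = {}
    for thr in cfg["grn_thresholds"]:
        g = clr.build_grn(clr_mat, tfs, float(thr))
        path = out / f"grn_threshold_{thr:g}.tsv"
        io.write_network(g, path)
        record("grn", f"threshold_{thr:g}", path)
        grns[float(thr)] = g

    work_grn = grns[min(grns)]  # densest GRN feeds the downstream stages

    log.info("stage specificity")
    tp = specificity.tau(expr1, truth.type_of_cell)
    tp.table.to_csv(out / "tau_species1.tsv", sep="\t")
    record("specificity", "tau", out / "tau_species1.tsv")

    log.info("stage hierarchy")
    hier_seed = child_seed(seed, 3)
    manifest["seeds"]["hierarchy"] = hier_seed
    if work_grn.number_of_edges() > 0:
        assignment = hierarchy.assign_levels(
            work_grn, n_levels=int(cfg["hierarchy_levels"]),
            sa_params=cfg["hierarchy_sa"] or None, seed=hier_seed)
        summary = hierarchy.level_summaries(assignment, work_grn, tau_profile=tp)
        summary.to_csv(out / "hierarchy_levels.tsv", sep="\t")
        io.write_json({"level_of": assignment.level_of,
                       "downward_fraction": assignment.downward_fraction,
                       "objective_value": assignment.objective_value},
                      out / "hierarchy.json")
        record("hierarchy", "assignment", out / "hierarchy.json")
        record("hierarchy", "summary", out / "hierarchy_levels.tsv")

    log.info("stage motifs")
    motif_seed = child_seed(seed, 4)
    manifest["seeds"]["motifs"] = motif_seed
    if work_grn.number_of_edges() >= 2:
        cat = motifs.motif_significance(work_grn, sizes=tuple(cfg["motif_sizes"]),
                                        n_random=int(cfg["motif_random"]),
                                        seed=motif_seed)
        cat.to_csv(out / "motifs.tsv", sep="\t")
        record("motifs", "catalog", out / "motifs.tsv")

    io.write_json(manifest, out / "manifest.json")
    return manifest
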