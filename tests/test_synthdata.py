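import itertools

import networkx as nx
import numpy as np
import pytest

from hemanet import (SpeciesPairConfig, generate_planted_grn,
                     generate_random_graph, generate_species_pair)
from hemanet.containers import CellClustering
from hemanet.synthdata import expected_type_means
from hemanet.zscore_net import cluster_de_zscores, zscore_correlation

TINY = dict(n_genes=120, n_cells_per_species=150, n_types=3, n_tfs=10,
            module_count=4, module_size=6)


def test_species_pair_seeded_determinism():
    cfg = SpeciesPairConfig(**TINY, seed=1)
    a1, a2, am, at = generate_species_pair(cfg)
    b1, b2, bm, bt = generate_species_pair(cfg)
    assert np.array_equal(a1.values, b1.values)
    assert np.array_equal(a2.values, b2.values)
    assert am.pairs == bm.pairs
    assert at.module_membership == bt.module_membership
    assert at.planted_edges == bt.planted_edges


def test_species_pair_no_rewiring_keeps_membership():
    cfg = SpeciesPairConfig(**TINY, cross_species_rewire_frac=0.0, seed=2)
    _, _, _, truth = generate_species_pair(cfg)
    assert truth.module_membership == truth.module_membership_sp2
    assert truth.rewired_genes == set()


def test_species_pair_rewiring_scrambles_requested_fraction():
    cfg = SpeciesPairConfig(**TINY, cross_species_rewire_frac=0.5, seed=2)
    _, _, _, truth = generate_species_pair(cfg)
    n_module_genes = len(truth.module_membership)
    assert len(truth.rewired_genes) == round(0.5 * n_module_genes)
    for g in truth.rewired_genes:
        assert truth.module_membership[g] != truth.module_membership_sp2[g]


def test_species_pair_structural_contracts():
    cfg = SpeciesPairConfig(**TINY, seed=3)
    e1, e2, homologs, truth = generate_species_pair(cfg)
    gene_universe = set(e1.gene_ids)
    for tf, tg in truth.planted_edges:
        assert tf in gene_universe and tg in gene_universe
        assert tf in truth.tf_ids
    for c in e1.cell_ids + e2.cell_ids:
        assert c in truth.type_of_cell
    assert len(homologs.pairs) == cfg.n_genes


@pytest.mark.parametrize("bad", [
    dict(n_genes=-5),
    dict(dropout_rate=1.5),
    dict(cross_species_rewire_frac=-0.1),
    dict(nb_dispersion=0.0),
    dict(module_size=1),
    dict(n_tfs=10_000),
])
def test_species_pair_config_validation(bad):
    with pytest.raises(ValueError):
        SpeciesPairConfig(**{**TINY, **bad})


def test_module_gene_dez_correlation_exceeds_background(small_pair, small_clusterings):
    """Genes planted in the same module correlate more strongly in DE
    z-score space than cross-module gene pairs."""
    e1, _, _, truth = small_pair
    dez = cluster_de_zscores(e1, small_clusterings[0])
    corr = zscore_correlation(dez)
    gi = {g: i for i, g in enumerate(corr.gene_ids)}
    modules = {}
    for g, m in truth.module_membership.items():
        modules.setdefault(m, []).append(g)
    within, between = [], []
    for m, genes in modules.items():
        for a, b in itertools.combinations(sorted(genes), 2):
            within.append(corr.R[gi[a], gi[b]])
    mods = sorted(modules)
    for m1, m2 in itertools.combinations(mods, 2):
        for a in modules[m1]:
            for b in modules[m2]:
                between.append(corr.R[gi[a], gi[b]])
    assert np.mean(within) > np.mean(between)


def test_poisson_limit_matches_configured_means():
    """Without dropout and with near-infinite dispersion the realized
    per-type mean counts match the configured means within 3 SE."""
    cfg = SpeciesPairConfig(n_genes=60, n_cells_per_species=900, n_types=3,
                            n_tfs=6, module_count=2, module_size=5,
                            dropout_rate=0.0, nb_dispersion=np.inf, seed=5)
    e1, _, _, truth = generate_species_pair(cfg)
    mu = expected_type_means(cfg)
    counts = np.asarray(e1.values, dtype=float)
    types = np.array([truth.type_of_cell[c] for c in e1.cell_ids])
    n_bad = 0
    for t in range(cfg.n_types):
        cells = np.flatnonzero(types == t)
        realized = counts[:, cells].mean(axis=1)
        se = counts[:, cells].std(axis=1, ddof=1) / np.sqrt(cells.size)
        n_bad += int(np.sum(np.abs(realized - mu[:, t]) > 3 * np.maximum(se, 1e-9)))
    # ~0.3% of gene/type combinations exceed 3 SE by chance; allow 2%
    assert n_bad <= 0.02 * cfg.n_genes * cfg.n_types


def test_planted_grn_fully_downward_when_frac_is_one():
    grn, levels = generate_planted_grn(12, 40, 3, downward_frac=1.0, seed=4)
    down = sum(1 for u, v in grn.edges
               if levels.get(u, 1) > levels.get(v, 1))
    assert down == grn.number_of_edges()


def test_planted_grn_downward_fraction_within_binomial_error():
    grn, levels = generate_planted_grn(60, 0, 4, downward_frac=0.9, seed=7)
    tftf = [(u, v) for u, v in grn.edges if v in levels]
    assert tftf
    obs = sum(1 for u, v in tftf if levels[u] > levels[v]) / len(tftf)
    assert abs(obs - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / len(tftf))


def test_planted_grn_level_contract_and_simplicity():
    grn, levels = generate_planted_grn(20, 50, 4, 0.8, seed=9)
    assert set(levels.values()) <= set(range(2, 6))  # 4 TF levels above targets
    assert all(u != v for u, v in grn.edges)
    assert nx.number_of_selfloops(grn) == 0
    for u, _ in grn.edges:
        assert grn.nodes[u]["is_tf"]


def test_planted_grn_rejects_bad_fraction():
    with pytest.raises(ValueError):
        generate_planted_grn(10, 10, 3, downward_frac=1.2, seed=0)


def test_erdos_exact_edge_count_simple_and_deterministic():
    g1 = generate_random_graph("erdos", 100, 250, seed=3)
    g2 = generate_random_graph("erdos", 100, 250, seed=3)
    assert g1.number_of_edges() == 250
    assert nx.number_of_selfloops(g1) == 0
    assert set(g1.edges) == set(g2.edges)


def test_erdos_infeasible_edge_count_raises():
    with pytest.raises(ValueError):
        generate_random_graph("erdos", 10, 46, seed=0)


def test_barabasi_has_heavy_tail():
    from hemanet.topology import degree_distribution_fit
    g = generate_random_graph("barabasi", 2000, 3, seed=5)
    slope, _ = degree_distribution_fit(g)
    assert slope < -1


def test_planted_modules_rank_above_background_across_seeds():
    """At the default study conditions, the mean within-module DE-z
    correlation exceeds the 90th percentile of all pairwise correlations
    in at least 80% of seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = SpeciesPairConfig(seed=seed)
        e1, _, _, truth = generate_species_pair(cfg)
        labels = CellClustering({c: truth.type_of_cell[c] for c in e1.cell_ids})
        corr = zscore_correlation(cluster_de_zscores(e1, labels))
        gi = {g: i for i, g in enumerate(corr.gene_ids)}
        modules = {}
        for g, m in truth.module_membership.items():
            modules.setdefault(m, []).append(g)
        within = [corr.R[gi[a], gi[b]] for genes in modules.values()
                  for a, b in itertools.combinations(sorted(genes), 2)]
        iu = np.triu_indices(len(corr.gene_ids), 1)
        hits += np.mean(within) > np.percentile(corr.R[iu], 90)
    assert hits >= 0.8 * n_seeds
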