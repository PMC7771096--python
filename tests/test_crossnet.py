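import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemanet.containers import CorrelationMatrix
from hemanet.crossnet import (conserved_overlap_test, diffk, diffk_pvalues,
                              enrichment_odds_ratio, gene_set_enrichment,
                              restrict_to_homologs, select_tails)
from hemanet.synthdata import HomologMap


def _net(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


def test_full_homolog_map_is_identity_restriction():
    a = _net([("h1", "h2"), ("h2", "h3")])
    b = _net([("m1", "m3")])
    hmap = HomologMap([("h1", "m1"), ("h2", "m2"), ("h3", "m3")])
    ra, rb = restrict_to_homologs(a, b, hmap)
    assert set(map(frozenset, ra.edges)) == set(map(frozenset, a.edges))
    assert set(map(frozenset, rb.edges)) == {frozenset({"h1", "h3"})}


def test_empty_map_annihilates_both_networks():
    a, b = _net([("x", "y")]), _net([("u", "v")])
    ra, rb = restrict_to_homologs(a, b, HomologMap([]))
    assert ra.number_of_edges() == 0 and rb.number_of_edges() == 0


def test_unmapped_endpoint_drops_edge():
    a = _net([("a1", "a2")])
    ra, _ = restrict_to_homologs(a, _net([]), HomologMap([("a1", "b1")]))
    assert ra.number_of_edges() == 0


def test_duplicate_mapping_rows_rejected():
    with pytest.raises(ValueError):
        HomologMap([("a", "b"), ("a", "c")])


def test_overlap_identical_networks_gives_minimal_p():
    g = nx.gnm_random_graph(40, 100, seed=1)
    res = conserved_overlap_test(g, g, n_perm=99, seed=0)
    assert res.observed_overlap == 100
    assert res.p_value == pytest.approx(1 / 100)


def test_overlap_disjoint_networks_is_unremarkable():
    nodes = range(1000)
    a = _net([(2 * i, 2 * i + 1) for i in range(50)])
    b = _net([(2 * i + 100, 2 * i + 101) for i in range(500, 550)])
    a.add_nodes_from(nodes)
    b.add_nodes_from(nodes)
    res = conserved_overlap_test(a, b, n_perm=99, seed=0)
    assert res.observed_overlap == 0
    assert res.p_value > 0.9


def test_overlap_null_mean_matches_er_closed_form():
    """Null overlap mean is |E1||E2|/C(n,2) for uniformly resampled pairs."""
    g1 = nx.gnm_random_graph(60, 200, seed=2)
    g2 = nx.gnm_random_graph(60, 300, seed=3)
    res = conserved_overlap_test(g1, g2, n_perm=300, seed=1)
    expected = 200 * 300 / math.comb(60, 2)
    assert abs(res.null_mean - expected) <= 3 * res.null_sd
    assert res.p_value >= 1 / 301


def test_overlap_requires_permutations():
    with pytest.raises(ValueError):
        conserved_overlap_test(_net([(1, 2)]), _net([(1, 2)]), n_perm=0)


def test_diffk_zero_for_equal_connectivity():
    g = _net([("a", "b"), ("b", "c")])
    table = diffk(g, g)
    assert np.allclose(table["diffk"], 0.0)


def test_diffk_hand_value_unnormalized():
    # k1 = 90, k2 = 0 with pseudo-count 10: log10(100) - log10(10) = 1
    hub = _net([("hub", f"t{i}") for i in range(90)])
    other = _net([(f"t{i}", f"t{i+1}") for i in range(90)])  # hub degree 0
    table = diffk(hub, other, normalize=False)
    assert table.loc["hub", "diffk"] == pytest.approx(
        math.log10(100) - math.log10(10))


def test_diffk_antisymmetric_under_species_swap():
    g1 = nx.gnm_random_graph(30, 60, seed=4)
    g2 = nx.gnm_random_graph(30, 90, seed=5)
    t12 = diffk(g1, g2)
    t21 = diffk(g2, g1)
    assert np.allclose(t12["diffk"], -t21["diffk"])


def test_diffk_rejects_empty_network():
    with pytest.raises(ValueError):
        diffk(_net([]), _net([(1, 2)]))


def _table(values):
    return pd.DataFrame({"diffk": values,
                         "k_species1": 0.0, "k_species2": 0.0,
                         "p_value": np.nan, "fdr": np.nan},
                        index=[f"g{i}" for i in range(len(values))])


@pytest.mark.parametrize("null_fit", ["moments", "central_quantile"])
def test_diffk_p_is_one_at_the_null_center(null_fit):
    rng = np.random.default_rng(6)
    vals = np.concatenate([rng.normal(0.2, 0.5, 99), [None]])
    vals[-1] = np.mean(vals[:-1].astype(float)) if null_fit == "moments" \
        else np.median(vals[:-1].astype(float))
    out = diffk_pvalues(_table(vals.astype(float)), null_fit=null_fit)
    assert out["p_value"].iloc[-1] == pytest.approx(1.0)


def test_diffk_pvalues_uniform_under_null():
    rng = np.random.default_rng(7)
    out = diffk_pvalues(_table(rng.normal(size=10_000)), null_fit="moments")
    ks = stats.kstest(out["p_value"], "uniform").statistic
    assert ks < 0.02


def test_bh_fdr_hand_case():
    out = diffk_pvalues(_table(np.linspace(-2, 2, 40)), null_fit="moments")
    # oracle: statsmodels BH equals the step-up hand computation
    p = out["p_value"].to_numpy()
    order = np.argsort(p)
    hand = np.empty_like(p)
    prev = 1.0
    for rank, idx in list(enumerate(order, start=1))[::-1]:
        prev = min(prev, p[idx] * len(p) / rank)
        hand[idx] = prev
    assert np.allclose(out["fdr"], hand)
    # the printed 4-value example, via the same step-up rule
    small = np.array([0.01, 0.02, 0.03, 0.04])
    expected = np.minimum.accumulate((small * 4 / np.arange(1, 5))[::-1])[::-1]
    assert np.allclose(expected, 0.04)


def test_diffk_pvalues_need_enough_genes():
    with pytest.raises(ValueError):
        diffk_pvalues(_table(np.arange(5.0)))


def test_tail_sizes_at_n100():
    rng = np.random.default_rng(8)
    top, bottom, conserved = select_tails(_table(rng.normal(size=100)))
    assert (len(top), len(bottom), len(conserved)) == (5, 5, 10)
    assert not top & bottom


def test_zero_diffk_gene_lands_in_conserved_set():
    vals = np.linspace(-3, 3, 20)
    vals[7] = 0.0
    _, _, conserved = select_tails(_table(vals), 0.1, 0.1, 0.1)
    assert "g7" in conserved


def test_tails_match_sort_oracle():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=20)
    table = _table(vals)
    top, bottom, conserved = select_tails(table, 0.2, 0.2, 0.3)
    order = np.argsort(-vals, kind="stable")
    assert top == {f"g{i}" for i in order[:4]}
    assert bottom == {f"g{i}" for i in np.argsort(vals, kind="stable")[:4]}
    assert conserved == {f"g{i}" for i in np.argsort(np.abs(vals), kind="stable")[:6]}


def test_tails_validation():
    with pytest.raises(ValueError):
        select_tails(_table(np.arange(100.0)), 0.5, 0.3, 0.3)
    with pytest.raises(ValueError):
        select_tails(_table(np.arange(5.0)), 0.05, 0.05, 0.1)


def _corr_matrix(n, seed):
    rng = np.random.default_rng(seed)
    R = rng.uniform(-1, 1, (n, n))
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R, [f"g{i}" for i in range(n)])


def test_odds_ratio_is_one_when_reference_is_all_pairs():
    corr = _corr_matrix(6, 10)
    ref = list(itertools.combinations(corr.gene_ids, 2))
    curve = enrichment_odds_ratio(corr, ref, cutoffs=[-0.5, 0.0, 0.5])
    assert np.allclose(curve["odds_ratio"].dropna(), 1.0)


def test_odds_ratio_counting_oracle():
    corr = _corr_matrix(6, 11)
    ref = [("g0", "g1"), ("g2", "g3"), ("g4", "g5")]
    cutoffs = [-0.8, -0.2, 0.2, 0.6]
    curve = enrichment_odds_ratio(corr, ref, cutoffs)
    pairs = list(itertools.combinations(range(6), 2))
    for row in curve.itertuples():
        n_all = sum(corr.R[i, j] > row.cutoff for i, j in pairs)
        n_ref = sum(corr.R[int(a[1]), int(b[1])] > row.cutoff for a, b in ref)
        if n_all == 0:
            assert np.isnan(row.odds_ratio)
        else:
            assert row.odds_ratio == pytest.approx((n_ref / 3) / (n_all / 15))


def test_odds_ratio_missing_above_the_maximum():
    corr = _corr_matrix(5, 12)
    curve = enrichment_odds_ratio(corr, [("g0", "g1")], cutoffs=[2.0])
    assert np.isnan(curve["odds_ratio"].iloc[0])


def test_odds_ratio_rejects_foreign_pairs():
    corr = _corr_matrix(4, 13)
    with pytest.raises(ValueError):
        enrichment_odds_ratio(corr, [("g0", "nope")], cutoffs=[0.0])


def test_enrichment_perfect_overlap_hits_hypergeometric_floor():
    universe = [f"g{i}" for i in range(20)]
    query = universe[:5]
    table = gene_set_enrichment(query, universe, {"set": set(query)})
    assert table.loc["set", "p_value"] == pytest.approx(1 / math.comb(20, 5))


def test_enrichment_independence_table_is_unremarkable():
    universe = [f"g{i}" for i in range(25)]
    query = universe[:5]           # 2x2 table 1,4 / 4,16
    aset = set(query[:1]) | set(universe[5:9])
    table = gene_set_enrichment(query, universe, {"s": aset})
    assert table.loc["s", "p_value"] > 0.5


def test_enrichment_validation():
    with pytest.raises(ValueError):
        gene_set_enrichment(["a"], [], {"s": {"a"}})
    with pytest.raises(ValueError):
        gene_set_enrichment(["a"], ["b"], {"s": {"b"}})


def test_odds_ratio_increases_with_cutoff_on_planted_edges(small_pair, small_clusterings):
    """Planted TF->target pairs are increasingly over-represented among
    highly correlated pairs as the correlation cutoff rises."""
    from hemanet.zscore_net import cluster_de_zscores, zscore_correlation
    e1, _, _, truth = small_pair
    corr = zscore_correlation(cluster_de_zscores(e1, small_clusterings[0]))
    ref = sorted({tuple(sorted(p)) for p in truth.planted_edges})
    curve = enrichment_odds_ratio(corr, ref, cutoffs=[0.0, 0.5, 0.8, 0.9])
    ors = curve["odds_ratio"].to_numpy()
    assert np.all(np.diff(ors) > 0)
    assert ors[-1] > 5 * ors[0]
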