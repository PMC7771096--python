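"""Network topology diagnostics.

Centralities (degree, betweenness, clustering, PageRank), density, average
shortest path on the largest component, small-world comparison against an
Erdős ensemble with matched node/edge counts, and the regression-style
scale-free diagnostic (log frequency vs log degree over log-spaced bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_seed


@dataclass
class SmallWorldResult:
    L_obs: float
    CC_obs: float
    L_null_mean: float
    L_null_sd: float
    CC_null_mean: float
    CC_null_sd: float
    L_ratio: float
    CC_ratio: float
    n_random: int
    is_small_world: bool


def centrality_profile(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, raw betweenness, clustering coefficient, PageRank.

    Betweenness is unnormalized shortest-path counting over unordered pairs;
    nodes of degree < 2 get clustering coefficient 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    nodes = list(net.nodes)
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)
    clu = nx.clustering(net)
    pr = nx.pagerank(net, alpha=0.85, tol=1e-10, max_iter=1000)
    return pd.DataFrame(
        {"degree": [deg[n] for n in nodes],
         "betweenness": [btw[n] for n in nodes],
         "clustering_coefficient": [clu[n] for n in nodes],
         "pagerank": [pr[n] for n in nodes]},
        index=pd.Index(nodes, name="gene"),
    )


def network_density(net: nx.Graph) -> float:
    """2E / (n(n-1)) — the share of realized over possible edges."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def _largest_component(net: nx.Graph) -> nx.Graph:
    comps = sorted(nx.connected_components(net),
                   key=lambda c: (-len(c), sorted(map(str, c))))
    return net.subgraph(comps[0])


def average_shortest_path(net: nx.Graph) -> float:
    """Mean shortest-path length over the largest connected component."""
    if net.number_of_edges() == 0:
        raise ValueError("network has no edges")
    comp = _largest_component(net)
    return float(nx.average_shortest_path_length(comp))


def small_world_odds(net: nx.Graph, n_random: int = 100, seed: int = 0,
                     l_ratio_max: float = 3.0,
                     cc_ratio_min: float = 5.0) -> SmallWorldResult:
    """L and CC ratios against Erdős graphs with the same node/edge counts.

    Small-world is flagged when the shortest-path ratio stays moderate
    (<= ``l_ratio_max``) while the clustering ratio is large
    (>= ``cc_ratio_min``).  Disconnected null draws use the
    largest-component convention for L.
    """
    if n_random < 1:
        raise ValueError("n_random must be at least 1")
    n, e = net.number_of_nodes(), net.number_of_edges()
    l_obs = average_shortest_path(net)
    cc_obs = float(nx.average_clustering(net))
    ls, ccs = np.empty(n_random), np.empty(n_random)
    for i in range(n_random):
        g = nx.gnm_random_graph(n, e, seed=child_seed(seed, i))
        ls[i] = average_shortest_path(g)
        ccs[i] = float(nx.average_clustering(g))
    l_mu, l_sd = float(ls.mean()), float(ls.std(ddof=1) if n_random > 1 else 0.0)
    c_mu, c_sd = float(ccs.mean()), float(ccs.std(ddof=1) if n_random > 1 else 0.0)
    l_ratio = l_obs / l_mu if l_mu > 0 else np.inf
    cc_ratio = cc_obs / c_mu if c_mu > 0 else np.inf
    return SmallWorldResult(l_obs, cc_obs, l_mu, l_sd, c_mu, c_sd,
                            float(l_ratio), float(cc_ratio), n_random,
                            bool(l_ratio <= l_ratio_max and cc_ratio >= cc_ratio_min))


def degree_distribution_fit(net: nx.Graph, n_bins: int | None = None):
    """Least-squares slope of log10(frequency density) on log10(degree).

    Degrees are pooled into log-spaced bins (zero-degree nodes excluded);
    empty bins are dropped.  Returns ``(slope, r_squared)``.  A heavy-tailed
    (scale-free-like) network yields a steep negative slope with high R².
    """
    degrees = np.array([d for _, d in net.degree() if d > 0], dtype=float)
    if np.unique(degrees).size < 3:
        raise ValueError("need at least 3 distinct positive degrees to fit")
    dmin, dmax = degrees.min(), degrees.max()
    if n_bins is None:
        n_bins = min(15, max(5, int(np.sqrt(np.unique(degrees).size) * 3)))
    edges = np.logspace(np.log10(dmin), np.log10(dmax), n_bins + 1)
    edges[-1] *= 1.0 + 1e-12  # include dmax in the last bin
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 populated degree bins; fit unstable")
    density = counts[keep] / widths[keep]
    res = stats.linregress(np.log10(centers[keep]), np.log10(density))
    return float(res.slope), float(res.rvalue**2)
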