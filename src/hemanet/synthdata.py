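"""Synthetic two-species single-cell data with planted network structure.

Emulates the inputs of a cross-species hematopoietic network study: UMI-count
matrices for two species over one-to-one homologous genes, discrete cell
types, planted co-expressed gene modules (whose members share per-type
activity and therefore correlate in cluster-pair DE z-score space), planted
TF->target edges inside modules, negative-binomial overdispersion and
Bernoulli dropout.  A configurable fraction of module memberships is
scrambled in the second species, creating a known conserved/divergent split
for differential-connectivity analyses.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._rng import substreams
from .containers import ExpressionMatrix, make_grn

# Effect-size constants on the log-mean scale (natural log).  Chosen once to
# give clearly detectable but not saturated DE signal at the default scale;
# see docs/methods.md.
BASELINE_LOG_MEAN = math.log(0.5)
BASELINE_LOG_SD = 0.8
TYPE_PROGRAM_EFFECT = 1.5      # elevation for a type's program genes
MODULE_TYPE_EFFECT_SD = 1.2    # per-module, per-type activity effect
MODULE_CELL_LATENT_SD = 0.3    # shared per-cell module activity jitter
N_PROGRAM_GENES_PER_TYPE = 20


@dataclass
class SpeciesPairConfig:
    """Study conditions for the paired-species generator."""

    n_genes: int = 2000
    n_cells_per_species: int = 1000
    n_types: int = 5
    n_tfs: int = 100
    module_count: int = 10
    module_size: int = 10
    cross_species_rewire_frac: float = 0.0
    dropout_rate: float = 0.3
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_cells_per_species", "n_types", "n_tfs",
                     "module_count", "module_size", "seed"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if name != "seed" and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must not exceed n_genes")
        if self.module_size < 2:
            raise ValueError("module_size must be at least 2")
        for name in ("cross_species_rewire_frac", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be positive")
        if self.module_count * self.module_size > self.n_genes:
            raise ValueError("modules cannot cover more genes than n_genes")
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")


@dataclass
class HomologMap:
    """One-to-one homolog pairs (species-1 id, species-2 id)."""

    pairs: list

    def __post_init__(self):
        self.pairs = [tuple(p) for p in self.pairs]
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("homolog map must be one-to-one")

    def to_species1(self) -> dict:
        return {b: a for a, b in self.pairs}


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure (species-1 gene namespace)."""

    module_membership: dict          # gene -> module id (species 1)
    planted_edges: set               # directed (TF, target) pairs
    type_of_cell: dict               # cell id -> type label (both species)
    type_specific_genes: dict        # type -> set of genes
    module_membership_sp2: dict = field(default_factory=dict)
    rewired_genes: set = field(default_factory=set)
    tf_ids: set = field(default_factory=set)


def _negbin_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    """NB draw with mean mu and size `dispersion` (var = mu + mu^2/r)."""
    if not np.isfinite(dispersion):
        return rng.poisson(mu)
    r = float(dispersion)
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _species_counts(rng, log_mu0, membership, beta, programs, types_of_cells,
                    dropout_rate, dispersion, module_ids):
    n_genes = log_mu0.size
    n_cells = types_of_cells.size
    logmu = np.tile(log_mu0[:, None], (1, n_cells))
    # type-program elevation
    for t, genes in programs.items():
        idx = np.fromiter(genes, dtype=int)
        cells = np.flatnonzero(types_of_cells == t)
        logmu[np.ix_(idx, cells)] += TYPE_PROGRAM_EFFECT
    # per-module, per-type activity plus shared per-cell latent factor
    mod_of_gene = np.full(n_genes, -1)
    for g, m in membership.items():
        mod_of_gene[g] = m
    latent = rng.normal(0.0, MODULE_CELL_LATENT_SD, size=(len(module_ids), n_cells))
    for mi, m in enumerate(module_ids):
        idx = np.flatnonzero(mod_of_gene == m)
        if idx.size == 0:
            continue
        effect = beta[mi, types_of_cells] + latent[mi]
        logmu[idx] += effect[None, :]
    mu = np.exp(logmu)
    counts = _negbin_counts(rng, mu, dispersion).astype(np.int32)
    if dropout_rate > 0:
        counts[rng.random(counts.shape) < dropout_rate] = 0
    return counts, mu


def _plant_structure(cfg: SpeciesPairConfig, rng_struct: np.random.Generator):
    """Draw the shared structural layer (modules, programs, effect sizes)."""
    module_ids = list(range(cfg.module_count))
    # modules: seed each with a TF (round-robin) then fill with other genes
    membership: dict[int, int] = {}
    pool = list(rng_struct.permutation(np.arange(cfg.n_tfs, cfg.n_genes)))
    for m in module_ids:
        if cfg.n_tfs > 0:
            membership[int(m % cfg.n_tfs)] = m
    for m in module_ids:
        need = cfg.module_size - sum(1 for v in membership.values() if v == m)
        for _ in range(max(need, 0)):
            membership[int(pool.pop())] = m

    # type programs from genes outside modules (keeps effects separable)
    non_module = [g for g in range(cfg.n_genes) if g not in membership]
    rng_struct.shuffle(non_module)
    programs: dict[int, set] = {}
    take = min(N_PROGRAM_GENES_PER_TYPE, max(len(non_module) // max(cfg.n_types, 1), 1))
    pos = 0
    for t in range(cfg.n_types):
        programs[t] = set(non_module[pos:pos + take])
        pos += take

    # species-2 membership: scramble a fraction of module genes
    membership2 = dict(membership)
    module_genes = sorted(membership)
    n_rewire = int(round(cfg.cross_species_rewire_frac * len(module_genes)))
    rewired: set[int] = set()
    if n_rewire > 0 and cfg.module_count > 1:
        chosen = rng_struct.choice(module_genes, size=n_rewire, replace=False)
        for g in chosen:
            others = [m for m in module_ids if m != membership[int(g)]]
            membership2[int(g)] = int(rng_struct.choice(others))
            rewired.add(int(g))

    log_mu0 = rng_struct.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=cfg.n_genes)
    beta = rng_struct.normal(0.0, MODULE_TYPE_EFFECT_SD,
                             size=(cfg.module_count, cfg.n_types))
    return module_ids, membership, membership2, rewired, programs, log_mu0, beta


def generate_species_pair(config: SpeciesPairConfig):
    """Generate paired-species expression with planted modules and edges.

    Returns ``(expr1, expr2, homolog_map, truth)``.  Gene ids are
    ``HS_Gxxxx`` / ``MM_Gxxxx``; the truth tables use the species-1
    namespace.
    """
    cfg = config
    rng_struct, rng_e1, rng_e2 = substreams(cfg.seed, 3)

    genes1 = [f"HS_G{i:04d}" for i in range(cfg.n_genes)]
    genes2 = [f"MM_G{i:04d}" for i in range(cfg.n_genes)]
    homologs = HomologMap(list(zip(genes1, genes2)))

    (module_ids, membership, membership2, rewired, programs,
     log_mu0, beta) = _plant_structure(cfg, rng_struct)

    # planted TF->target edges: module TFs regulate their module co-members
    planted = set()
    for g, m in membership.items():
        if g < cfg.n_tfs:
            for h, m2 in membership.items():
                if m2 == m and h != g:
                    planted.add((genes1[g], genes1[h]))

    n_cells = cfg.n_cells_per_species
    types_of_cells = np.arange(n_cells) % cfg.n_types  # near-even split
    cells1 = [f"HS_C{i:05d}" for i in range(n_cells)]
    cells2 = [f"MM_C{i:05d}" for i in range(n_cells)]

    counts1, _ = _species_counts(rng_e1, log_mu0, membership, beta, programs,
                                 types_of_cells, cfg.dropout_rate,
                                 cfg.nb_dispersion, module_ids)
    counts2, _ = _species_counts(rng_e2, log_mu0, membership2, beta, programs,
                                 types_of_cells, cfg.dropout_rate,
                                 cfg.nb_dispersion, module_ids)

    expr1 = ExpressionMatrix(counts1, genes1, cells1, species="species1")
    expr2 = ExpressionMatrix(counts2, genes2, cells2, species="species2")

    type_of_cell = {c: int(t) for c, t in zip(cells1, types_of_cells)}
    type_of_cell.update({c: int(t) for c, t in zip(cells2, types_of_cells)})

    truth = PlantedTruth(
        module_membership={genes1[g]: m for g, m in membership.items()},
        planted_edges=planted,
        type_of_cell=type_of_cell,
        type_specific_genes={t: {genes1[g] for g in gs} for t, gs in programs.items()},
        module_membership_sp2={genes1[g]: m for g, m in membership2.items()},
        rewired_genes={genes1[g] for g in rewired},
        tf_ids={genes1[g] for g in range(cfg.n_tfs)},
    )
    return expr1, expr2, homologs, truth


def expected_type_means(config: SpeciesPairConfig):
    """Configured per-gene, per-type mean counts for species 1 (no dropout).

    Mirrors the generative model's mean structure exactly (including the
    lognormal correction for the per-cell latent module factor) so tests can
    compare realized means against configured ones.
    """
    cfg = config
    rng_struct, _, _ = substreams(cfg.seed, 3)
    _, membership, _, _, programs, log_mu0, beta = _plant_structure(cfg, rng_struct)

    means = np.tile(np.exp(log_mu0)[:, None], (1, cfg.n_types))
    for t, genes in programs.items():
        for g in genes:
            means[g, t] *= math.exp(TYPE_PROGRAM_EFFECT)
    latent_corr = math.exp(0.5 * MODULE_CELL_LATENT_SD**2)
    for g, m in membership.items():
        means[g, :] *= np.exp(beta[m, :]) * latent_corr
    return means


def generate_planted_grn(n_tf: int, n_target: int, n_levels: int,
                         downward_frac: float, edges_per_node: int = 3,
                         seed: int = 0):
    """Planted hierarchical GRN for the annealing layout.

    TFs are assigned true levels 2..n_levels+1 (targets sit at level 1,
    below every TF).  Each TF-TF edge connects two TFs from *different*
    levels and is oriented high->low with probability ``downward_frac``
    (low->high otherwise); each target receives ``edges_per_node`` incoming
    edges from random TFs.  Simple digraph, no self-loops.

    Returns ``(grn, true_levels)``.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if not 0.0 <= downward_frac <= 1.0:
        raise ValueError("downward_frac must lie in [0, 1]")
    if n_tf < 2:
        raise ValueError("need at least 2 TFs")
    rng = np.random.default_rng(int(seed))
    tfs = [f"TF{i:03d}" for i in range(n_tf)]
    targets = [f"T{i:04d}" for i in range(n_target)]
    # pyramidal occupancy: lower TF levels hold more TFs (largest-remainder
    # allocation of weights n_levels..1 from bottom level 2 to the top)
    weights = np.arange(n_levels, 0, -1, dtype=float)
    raw = weights / weights.sum() * n_tf
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts)):
        if counts.sum() >= n_tf:
            break
        counts[i] += 1
    while np.any(counts == 0):  # every level needs at least one TF
        counts[np.argmin(counts)] += 1
        counts[np.argmax(counts)] -= 1
    true_levels = {}
    pos = 0
    for li, c in enumerate(counts):
        for tf in tfs[pos:pos + c]:
            true_levels[tf] = 2 + li
        pos += c

    edges = []
    seen = set()
    n_tftf = n_tf * edges_per_node
    attempts = 0
    while len(edges) < n_tftf and attempts < 50 * n_tftf:
        attempts += 1
        i, j = rng.integers(0, n_tf, size=2)
        if i == j or true_levels[tfs[i]] == true_levels[tfs[j]]:
            continue
        hi, lo = (tfs[i], tfs[j]) if true_levels[tfs[i]] > true_levels[tfs[j]] else (tfs[j], tfs[i])
        if rng.random() < downward_frac:
            u, v = hi, lo
        else:
            u, v = lo, hi
        if (u, v) in seen:
            continue
        seen.add((u, v))
        edges.append((u, v))
    for t in targets:
        srcs = rng.choice(n_tf, size=min(edges_per_node, n_tf), replace=False)
        for s in srcs:
            edges.append((tfs[s], t))

    grn = make_grn(edges, tfs)
    return grn, true_levels


def generate_random_graph(model: str, n_nodes: int, n_edges_or_m: int,
                          directed: bool = False, seed: int = 0):
    """Seeded reference random graphs (Erdős G(n,m) or Barabási–Albert)."""
    if model == "erdos":
        max_e = n_nodes * (n_nodes - 1) if directed else n_nodes * (n_nodes - 1) // 2
        if n_edges_or_m > max_e:
            raise ValueError(
                f"{n_edges_or_m} edges infeasible for a simple graph on {n_nodes} nodes")
        return nx.gnm_random_graph(n_nodes, n_edges_or_m, seed=int(seed),
                                   directed=directed)
    if model == "barabasi":
        if directed:
            raise ValueError("barabasi model is undirected here")
        return nx.barabasi_albert_graph(n_nodes, n_edges_or_m, seed=int(seed))
    raise ValueError(f"unknown model {model!r}")
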