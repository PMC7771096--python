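# Methods

`hemanet` implements a cross-species workflow for inferring and comparing
gene regulatory networks from single-cell expression data, together with a
synthetic-data generator that lets every stage be exercised and validated
without external downloads. This note records the models, conventions and
numerical choices behind each stage.

## Co-expression from cluster-pair DE z-scores

Raw single-cell profiles are dominated by dropout, so gene-gene
correlations are not computed on expression values. Instead each gene is
summarized by one signed z-score per unordered pair of cell clusters
(X clusters give X(X−1)/2 comparisons), and correlations are computed
between these z-score vectors. The DE statistic is a Wilcoxon rank-sum
normal-approximation z with tie correction, signed so that a positive value
means higher expression in the first cluster of the pair (clusters ordered
by label). Rank statistics were chosen because they need no fitted noise
model and are insensitive to the zero inflation that motivates the design;
a Welch-t alternative is available via `statistic="welch"`. Genes with zero
variance in both clusters get z = 0, and constant z-vectors get correlation
0 to every other gene (instead of NaN).

The network retains the top-K correlations. Ranking is by absolute value by
default (co-repression counts as co-expression); a signed option exists.
Ties at the cutoff are broken by lexicographic gene-pair order so edge sets
are reproducible. A fixed-threshold mode returns exactly the edges a top-K
of the above-threshold count would.

## CLR background correction and the directed GRN

Each correlation R_ij is rescored against the distributions of row i and
column j:

    z_i = (R_ij − mean_i) / sd_i,   z_j = (R_ij − mean_j) / sd_j,
    z(g_i, g_j) = sqrt(z_i² + z_j²).

Conventions: the diagonal self-correlation of 1 is excluded from the
row/column mean and sd (including it would bias every row mean upward);
sd is the population standard deviation; rows with sd = 0 contribute z = 0.
The classic CLR variant that clamps negative z at 0 before squaring is
available via `clamp_negative=True`; the default leaves the scores
unclamped. CLR is applied to the full correlation matrix, not only to
retained co-expression edges.

Pairs with pseudo z at or above a threshold become edges when at least one
member is an annotated transcription factor: (TF, non-TF) gives one
TF→target edge; (TF, TF) gives both orientations, since the correlation
carries no directional information; pairs with no TF are dropped as likely
indirect associations. Thresholds 5 (stringent) and 3 (permissive) are the
conventional working points.

## Cross-species comparison

Networks are first projected onto a one-to-one homolog map and relabeled to
a shared namespace. Conservation of edges is tested by counting shared
unordered pairs against a null that resamples both edge sets uniformly
among all pairs on the union node set (same node and edge counts); the
Monte-Carlo p is (1 + #{null ≥ obs})/(n_perm + 1), so it is never zero.

Differential connectivity per gene is

    DiffK = log10(k₁ + 10) − log10(k₂ + 10)

computed on degrees rescaled to a common mean degree (the average of the
two networks' means). The rescaling pins down the otherwise loose notion of
"normalizing for network size" while preserving the meaning of the +10
pseudo-count across densities; `normalize=False` gives the raw-degree
formula. The log base (10 by default, natural optional) affects only the
scale: ranks and tail memberships are base-invariant.

DiffK values are approximately normal; p-values are two-sided normal tails
against a fitted null. The default fit (`central_quantile`) estimates the
null mean from the median and the sd from the IQR/1.349, i.e. from the
uncontaminated center of the distribution — a deliberately simple stand-in
for maximum-likelihood empirical-null fitting with the same intent. A plain
moments fit is available. FDR is Benjamini–Hochberg. Tail selection takes
the top and bottom floor(5% · N) by DiffK and the bottom floor(10% · N) by
|DiffK| as the conserved set, with lexicographic tie-breaks.

Validation against reference edge sets uses the odds ratio
(fraction of reference pairs with R > c) / (fraction of all unordered pairs
with R > c) over a cutoff grid; cutoffs exceeded by no pair at all are
reported as missing. Gene-set enrichment is a one-sided Fisher exact test
on the standard 2×2 table.

## Topology

Centralities come from networkx: exact degree, unnormalized shortest-path
betweenness (hand-checkable counts; a normalized option is a flag away),
local clustering, and PageRank (damping 0.85, tolerance 1e−10). Density is
2E/(n(n−1)). Average shortest path is computed over the largest connected
component (ties between components broken by size then lexicographic node
order); the same convention applies inside the Erdős null ensemble of the
small-world comparison, which matches node and edge counts exactly. The
small-world flag defaults to L_ratio ≤ 3 and CC_ratio ≥ 5. The scale-free
diagnostic regresses log10 frequency density on log10 degree over
log-spaced bins (empty bins dropped, zero-degree nodes excluded); it is a
descriptive diagnostic, not a likelihood-based power-law test.

## Specificity and active subnetworks

Tau uses per-type mean log1p expression x_i, normalizes by the maximum and
averages 1 − x̂ over the other types; 0 means ubiquitous, 1 single-type.
log1p avoids −∞ on zeros while keeping the formula unchanged on positive
data. Genes with all-zero expression get tau = 0. The specificity flag uses
tau > 0.8 and assigns the highest-expressing type. Per-type z-scores
standardize each gene's per-type means (sample sd) with one-sided normal
p-values.

Active-subnetwork search scores a connected gene set by
z_A = Σ z_g / sqrt(k), with z_g = Φ⁻¹(1 − p_g) (multiple p-value columns
combined by Stouffer's method), corrected against the Monte-Carlo mean and
sd of 1000 random same-size gene sets: s_A = (z_A − μ_k)/σ_k. When σ_k = 0
(all p equal) the corrected score is defined as 0. The search is simulated
annealing over gene inclusion restricted to connected sets: a move either
adds a gene adjacent to the current set or removes a non-articulation
member, with Metropolis acceptance and geometric cooling (T₀ = 1, factor
0.995, 10⁵ iterations by default); the first restart is seeded at the
highest-z gene, the rest at random nodes, and the best non-overlapping
results are returned. p-values of exactly 0 are rejected; p is clipped to
[1e−300, 1 − 1e−16] before the quantile transform.

## Hierarchy

Non-TF targets occupy level 1; TFs are assigned levels 2..n_levels
(default 4 levels in total) by simulated annealing that maximizes the
number of TF→TF edges running from a higher to a lower level. TF→target
edges are downward under any assignment and are therefore excluded from the
objective but included in the reported downward fraction. Moves reassign
one random TF to a random different level with incremental objective
updates; defaults are T₀ = 1, cooling 0.995, 2×10⁵ moves and 5 restarts,
keeping the best assignment seen. Equally optimal layouts are resolved by
the seeded search; alternative optima can be explored by seed variation.
The collaboration score of a TF is the fraction of its targets that are
also targeted by at least one other TF. Level summaries report TF counts,
mean collaboration, annotation-set fractions (both per-level gene counts
are in the table, so TF-only or all-gene denominators can be formed), mean
interaction degree and mean tau.

## Motifs

Subgraph identities use the mfinder bitmask convention: the id of a k-node
directed subgraph is the minimum over all k! relabelings of the row-major
adjacency bitmask Σ 2^(i·k+j); the feed-forward loop is 38, the bi-fan 204.
The census enumerates each weakly-connected induced 3- or 4-node subgraph
exactly once (ESU); disconnected patterns are excluded and roles (TF vs
target) are not distinguished. The null rewires the GRN by double-edge
swaps — (a→b, c→d) becomes (a→d, c→b) unless it would create a self-loop
or duplicate — with 10 attempted swaps per edge, preserving every node's
in- and out-degree exactly. Significance per pattern uses the empirical
upper-tail p (valid at small counts) plus the z-score against the null
mean/sd; a pattern is a motif when occurrence > 5, p < 0.05 and z > 2.
When the null sd is 0, z is 0 if the observed count equals the null mean
and is reported as a ±1e6 sentinel otherwise.

## Synthetic data

The generator emulates paired-species UMI-count matrices over one-to-one
homologous genes. Counts are negative binomial with a log-link mean:
baseline log-mean N(log 0.5, 0.8²) per gene, a +1.5 log-unit elevation for
each type's program genes (20 per type, drawn outside modules so the two
effects stay separable), a per-module per-type activity effect
N(0, 1.2²) shared by module members (this is what makes module genes
correlate in DE z-score space), and a shared per-cell module latent factor
N(0, 0.3²). Dispersion defaults to 2 (variance μ + μ²/2); an infinite
dispersion gives the Poisson limit used by the mean-recovery test. Dropout
is independent Bernoulli zero-masking at rate 0.3. Cell types are assigned
near-evenly. Cross-species divergence scrambles the module membership of a
configurable fraction of module genes in species 2, creating a known
conserved/divergent split for DiffK recovery. Each module is seeded with a
TF whose planted edges point at its module co-members, giving a reference
edge set for odds-ratio validation. Defaults are 2000 genes, 1000 cells per
species, 5 types, 100 TFs and 10 modules of 10 genes; effect sizes were
chosen once to give clearly detectable but unsaturated signal and are not
tuned per test. The generator does not model batch effects, doublets,
UMI collapsing or read-level noise, so passing tests demonstrate method
correctness and recovery under this idealized model, not performance on
real data.

The planted hierarchical GRN assigns TFs to levels with pyramidal
occupancy (largest-remainder allocation of weights n..1 from bottom to
top — the shape regulatory hierarchies empirically take), orients each
TF-TF edge (always between distinct levels) downward with probability
`downward_frac`, and attaches each target to `edges_per_node` random TFs.
Reference random graphs are Erdős G(n,m) (exact edge count) and
Barabási–Albert preferential attachment, both seeded.

All generators are pure functions of their configuration and a single
integer seed; internal substreams are derived with `SeedSequence` so
adding a stage never perturbs earlier draws.

## Problem sizes used in the test suite

Unit and property tests run on reduced problem sizes chosen as the
package's own testing conditions: species pairs of 120–300 genes and
150–250 cells for structural checks, the full default scale (2000 genes ×
1000 cells, 10 seeds) for the parameter-recovery suite, 200-node graphs
for subnetwork recovery, 30–90-node digraphs with 60–200 rewired nulls for
motif calibration, and 30–60 TF planted hierarchies. Brute-force oracles
(subset census, exhaustive level assignment, path-counting betweenness,
per-entry CLR evaluation) are exact and independent of the implementation
paths they verify.

## Known limitations

* Cluster labels are an input; no clustering is performed.
* Only the correlation-based CLR variant is implemented (no mutual
  information), and only two-species comparisons.
* The ER resampling null for edge overlap ignores degree structure; a
  degree-preserving alternative exists for motif analysis but the overlap
  test's null is intentionally the simple matched-size ensemble.
* The empirical null for DiffK assumes the central mass is null; heavy
  contamination of the center would bias p-values.
* The scale-free diagnostic is a regression slope, not a model comparison.
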