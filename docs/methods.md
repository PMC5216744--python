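# Methods

## Model

`smirnbi` scores candidate small-molecule⇄miRNA regulations by two-step
resource diffusion (network-based inference with resource allocation) on
the bipartite regulation graph. With X the m×n molecule–miRNA incidence
matrix, A = [[0, X], [Xᵀ, 0]] the order-(m+n) adjacency and
B(i,j) = A(i,j)/Σ_l A(i,l) the row-stochastic transfer matrix, the final
resource matrix is F = A·B². Row i of F is the outcome of: place one unit
of resource on each neighbour of node i, then twice let every node split
its resource equally among its neighbours. The implementation is dense
`numpy` matrix algebra; at the scale these curated networks reach (a few
hundred nodes per side) sparsity buys nothing and dense code is simpler to
verify. A literal node-by-node spreading simulation is kept in the test
suite as an independent oracle and the two agree to < 1e-12 on randomly
drawn networks.

Assumptions worth stating explicitly:

- **The diffusion is undirected and unlabeled.** Up/down regulation labels
  are carried on edges for reporting, degree breakdowns and subnetwork
  colouring, but do not influence scores. A sign-aware diffusion is a
  different model, out of scope here.
- **Edges are binary.** Multiple literature reports of the same pair
  collapse to one edge before any computation.
- **Isolated nodes are legal.** A node whose edges were all removed as
  conflicts keeps its place in the network; its transfer-matrix row is
  all-zero (no resource leaves it), and querying it returns an empty result
  flagged `unpredictable` rather than an error — with no topological links
  there is nothing to diffuse from.

### A symmetry the pooled evaluation inherits

B is the transition matrix of a random walk reversible with respect to the
degree distribution: d_i B(i,j) = d_j B(j,i). Since F = A·B² = D·B³ (D the
degree diagonal), reversibility gives F(i, m+j) = F(m+j, i) — **F is
symmetric**, so the score a molecule's row assigns to a miRNA equals the
score the miRNA's row assigns back. Consequently, with pooled scoring over
exhaustive negatives the two cross-validation "directions" produce
identical AUCs up to floating-point rounding. Direction-dependent AUCs can
only arise from asymmetric grouping of positives/negatives (e.g. per-query
averaging, where the two sides average over different query sets); both
modes are provided (`pooling="pooled"` is the default, `"per_query"` the
option).

## Score post-processing

Per query, raw scores over the entire opposite class are min-max rescaled
to [0, 1]. Known links are included in the rescaling window, so the maximum
(std 1.0) is typically a known link; the novel-prediction threshold
(default 0.1, the conventional operating point for these scores) is applied
to novel candidates only, afterwards. When every raw score is equal — e.g.
a degree-1 query in a tiny component — there is no spread to rescale: all
standardized scores are set to 0 and a degeneracy flag is raised rather
than manufacturing an arbitrary 1.0. Novel candidates are ranked by
standardized score with lexicographic tie-breaks, so output files are
byte-reproducible.

## Cross-validation

Repeated k-fold edge holdout, defaults 10 folds × 100 repeats (the CLI
exposes both; the shipped calibration and acceptance runs use 5 repeats at
desk scale). Per fold: rebuild the training incidence from the remaining
edges (node sets unchanged), recompute B and F, then score

- positives: the held-out edges of the fold;
- negatives: **all** pairs absent from the full network — exhaustive, not
  sampled, so the AUC is deterministic given the split. Training edges are
  never scored.

A held-out edge whose query node lost all its training links scores 0 and
stays in the positive pool (it is logged); dropping it would flatter the
model. AUC is the Mann–Whitney statistic with ties counted ½, computed by
rank sums (`scipy.stats.rankdata`); an exhaustive pairwise brute-force
count backs it in tests. Each repeat derives an independent RNG stream from
`(seed, repeat)` via `numpy.random.SeedSequence`, so single repeats are
individually reproducible.

Raw (not standardized) scores enter the AUC: per-query min-max is
rank-preserving within a query but not across the pooled queries of a fold.

## Network construction rules

- Duplicate (molecule, miRNA, direction) records collapse to one edge.
- A pair reported both up and down is a conflict: the default policy drops
  the pair entirely; `keep_unknown` retains one direction-less edge.
- A pair reported with a known direction plus direction-less records
  resolves to the known direction (only up-vs-down counts as conflict).
- miRNA–target-gene pairs: one record per pair after merging, labelled
  `strong` if any supporting record was strong (low-throughput validation
  dominates high-throughput).

## Downstream analyses

**Degrees** count deduplicated edges, optionally restricted to up- or
down-labelled edges; for fully labelled networks global = up + down per
node. **Projection** links two molecules iff they co-regulate ≥ 1 miRNA,
weight = number of shared miRNAs; module detection ignores the weights.

**Module detection** implements the MCODE procedure: vertex weight =
k × density of the highest k-core of the closed neighbourhood (vertices
under the degree cutoff are unweighted); complexes grow from the
highest-weight unused seed by breadth-first search up to `max_depth`,
admitting vertices with weight ≥ seed-weight × (1 − node score cutoff);
complexes lacking a 2-core are discarded; haircut prunes singly connected
members. Defaults: node score cutoff 0.2, max depth 5, degree cutoff 2,
haircut on, fluff off — the standard defaults of the Cytoscape plugin this
procedure originates from. Module score = density × size, and modules are
reported in decreasing score order with deterministic tie-breaks.

**Subnetwork extraction** restricts miRNA–gene pairs to a miRNA subset
(e.g. miRNAs co-regulated by ≥ 3 molecules of interest) and an optional
hub-targeting filter, then removes nodes with fewer than `min_pairs`
incident pairs. The pruning iterates to a fixed point by default: a removal
can push a surviving node below threshold, so single-pass output (offered
via `single_pass=True`) need not honour its own threshold. Fixed-point
output is idempotent and monotone in the threshold; both properties are
tested on random networks.

**Enrichment** is a plain hypergeometric over-representation test per gene
set (sets intersected with the universe first) with Benjamini–Hochberg
adjustment across sets. The universe defaults to all genes of the merged
target network. No attempt is made to match any particular enrichment
web-tool's p-values, which depend on its pathway-database version.

## Synthetic data

The planted-block generator emulates the modular structure of real curated
regulation networks, where molecules sharing a mechanism of action regulate
overlapping miRNA sets: molecules and miRNAs are assigned round-robin to
matched blocks; within-block pairs are edged with `p_in`, cross-block pairs
with `p_out`; directions are i.i.d. up with probability 0.56, the rough
up:down proportion seen in curated regulation collections. Defaults — 40
molecules, 100 miRNAs, 5 blocks, p_in 0.35, p_out 0.02, seed 42, ≈ 340
edges — are the package's standard study conditions: block sizes and
densities at which the planted structure is clearly learnable yet single
miRNAs still have realistic low degrees (2–8). The Erdős–Rényi generator at
matched density is the structureless null used to calibrate the CV
protocol: planted networks score mean AUC ≈ 0.76, the null ≈ 0.49.

What the generator does **not** emulate: scale-free degree tails, hub
molecules spanning blocks, curation biases (well-studied miRNAs accumulate
edges), direction structure correlated with topology, and molecule-name
synonymy. Passing tests on these fixtures therefore demonstrate
correctness of the algorithms and calibration of the protocol, not
expected performance on any particular real curated network.

## Numerical choices and degenerate inputs

- Zero-degree rows of B are exactly zero (no 0/0); conservation then holds
  exactly: row sums of F equal node degrees to within 1e-9.
- Standardisation of a constant score vector returns zeros plus a flag.
- All ranking ties (candidates, top-k degree lists, hub genes, module
  seeds) break lexicographically, making every output file a pure function
  of inputs and seed.
- Fold sizes differ by at most one (`numpy.array_split` of a seeded
  permutation).
- Thresholds are validated (`0 ≤ threshold ≤ 1`, `folds ≥ 2`,
  `min_pairs ≥ 1`); malformed table rows are collected and reported
  together with line numbers rather than aborting at the first.

## Limitations

- Direction-aware (signed) diffusion is not implemented; direction labels
  are descriptive only.
- Out-of-network molecules cannot be queried: the model needs at least one
  existing link to seed the diffusion.
- Dense algebra bounds practical network size to a few thousand nodes per
  side; beyond that a sparse refactor would be needed.
- The per-query pooling mode can yield undefined folds on tiny networks
  (a query with no negatives); such folds are NaN and excluded from the
  aggregate.
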