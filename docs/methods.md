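# Methods

## Model and procedure

`netstab` treats module detection in a correlation network as an estimation
problem with two coupled unknowns: the graph (determined by the hard
threshold t on the absolute Pearson correlation) and its partition into
modules. Both are re-estimated under resampling of the observations, and
reproducibility of the partition is the criterion for choosing t.

**Graph construction.** From an N × p data matrix the Pearson correlation
matrix is estimated and an edge placed wherever `|C(i, j)| > t`, strictly:
a correlation exactly equal to t yields no edge. Any t ≥ 1 legally produces
an edgeless graph; isolated nodes are retained throughout and are always
their own (singleton) modules. A constant column is rejected with an error
naming the variable, since its correlations are undefined; missing values
are rejected rather than silently handled pairwise.

**Module detection.** Fast-greedy (CNM) agglomerative modularity
optimization, delegated to igraph's C implementation: starting from
singletons, the merge with the largest modularity gain is applied
repeatedly, and the dendrogram is cut at the level of maximal Q,

    Q = Σ_i (e_ii − s_i²),

where e_ij is the fraction of edge endpoints joining modules i and j and
s_i = Σ_j e_ij. The `modularity` function in this package evaluates Q
directly from the edge list with the endpoint (Newman) convention — each
within-module edge contributes fully to e_ii, each cross edge half to e_ij
and half to e_ji — which makes Q identical to the igraph/networkx value;
tests cross-check it against networkx and against a from-scratch
adjacency-matrix evaluation. Detection is deterministic: identical graphs
yield identical partitions (igraph's internal, fixed merge order breaks
ties). An edgeless graph short-circuits to the all-singleton partition,
since Q is undefined without edges.

**Bootstrap.** The nodes (variables) are fixed; sampling uncertainty enters
through the subjects. A replicate therefore redraws the N rows with
replacement, re-estimates the correlation matrix, thresholds it at the same
t, and re-detects modules. A degenerate replicate — some variable constant
across the drawn rows — is discarded with a warning and redrawn so that B
is preserved, aborting after 10·B discards. (For continuous data this is
essentially impossible unless N is tiny; the policy exists so that the
pipeline fails loudly rather than silently on pathological inputs.)

**Stability estimates.** For partitions ℳ, ℳ' on the same nodes, the
node-wise agreement is the Jaccard coefficient of the two modules containing
the node; partition agreement is its mean over nodes. Node stability is the
mean agreement of the node's reference module across the B replicates;
module stability is the mean node stability over the module's members; the
overall stability is the mean over all nodes, which algebraically equals the
mean agreement of the replicates with the reference — both identities are
asserted at 1e−12 on every constructed report. All quantities lie in (0, 1]
because a node always belongs to both modules being compared.

**Threshold selection.** Stability conditional on one reference is not
comparable across edge densities (both the complete and the edgeless graph
are perfectly stable), so selection uses the unconditional observed
stability S_obs(t) — the mean agreement over all unordered pairs among the
B+1 partitions — referenced against a null expectation in the spirit of the
gap statistic. The null ensemble holds m graphs with exactly the observed
degree sequence but randomized wiring, generated by double-edge-swap MCMC
(10·|E| attempted swaps per graph; swaps creating self-loops or multi-edges
are rejected, so degrees are conserved exactly — asserted every run).
E[S_null(t)] is the mean pairwise agreement among the m null partitions,
and the profile statistic is S^Δ(t) = S_obs(t) − E[S_null(t)], maximized
over the grid with ties broken toward the smaller t (under-thresholding has
the milder consequence for module recovery). An edgeless threshold is
processed, not skipped: all partitions are singletons, S_null is exactly 1
(an edgeless graph randomizes to itself), and the threshold is flagged in
the diagnostics.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `thresholds` | 0.30–0.90 step 0.05 | simulation-style grid; a wider 0.20–0.90 grid (`APPLICATION_GRID`) suits noisier observational data whose correlations run lower |
| `B` | 100 | bootstrap replicates per threshold; conventional bootstrap scale, halved to 50 in the benchmark runs below |
| `m` | 50 | null graphs per threshold; 50 graphs give 1,225 pairwise agreements, which stabilizes E[S_null] at desk cost |
| swap count | 10·\|E\| attempted | common mixing heuristic for double-edge-swap randomization |
| `w` (GGM sampler) | 0.3 | partial-association strength on edges; keeps the precision matrix diagonally dominant, hence positive definite, for any graph |

All randomness flows from one master seed through `numpy` `SeedSequence`
substreams: data simulation, the bootstrap at each threshold, and the null
ensemble at each threshold draw from independent children, so changing m
does not perturb the bootstrap draws and runs are bit-reproducible.

## The synthetic generator

The block-diagonal model is the ground truth for evaluation: p variables in
equal blocks (a non-divisible p spreads the remainder over the leading
blocks), correlation α within a block, β between blocks, unit diagonal;
positive definiteness is checked by the smallest eigenvalue at
construction. Data are exact multivariate-normal draws via the Cholesky
factor. Any t in [β, α) applied to the *true* matrix recovers exactly the
block partition, so threshold selection can be scored: detected modules at
t_opt are compared with the true blocks via the adjusted Rand index
(scikit-learn's implementation, cross-checked in tests against a
from-scratch pair-counting oracle).

What the generator does *not* emulate: heavy tails, non-linear dependence,
missing data, unequal variances, hub-dominated or scale-free connectivity,
and overlapping modules — all common in real omics data. Passing the
benchmark therefore shows that the selection machinery recovers planted,
well-separated Gaussian block structure; it does not certify performance on
data violating those assumptions, where correlations are weaker and
stability values run lower across the board.

A generic Gaussian-graphical-model sampler (`ggm_sample`) is included as
plumbing for studies whose ground truth is a conditional-independence graph
rather than a block covariance: it builds a diagonally dominant precision
matrix on the graph's sparsity pattern, inverts, rescales to unit variance
and samples.

## Scoring conventions at the selected threshold

At small N and a high selected threshold, a few variables typically end up
*isolated* — none of their sample correlations clears t, usually because the
variable's own noisy draw depresses all of its correlations at once. An
isolated node is necessarily a singleton module and makes no module claim,
so the benchmark reports (a) the module count at t_opt excluding
isolated-node singletons and (b) the adjusted Rand index computed on the
nodes connected at t_opt. The full-partition ARI (isolates included) is
always computed alongside and carried in every experiment record; the
comparison against the Bonferroni p-value baseline uses the full-partition
score for both methods so neither is favored.

The baseline itself: edges where the two-sided p-value of the correlation
t-statistic (N−2 degrees of freedom), Bonferroni-multiplied by the
p(p−1)/2 tested pairs, falls below 0.05 — followed by the same fast-greedy
detection, so the comparison isolates the graph-construction rule.

## Benchmark scale

The packaged benchmark (tests and `scripts/acceptance.py`) runs the full
pipeline on p = 100, 10 blocks, β = 0.1 at (N, α) ∈ {(30, 0.8), (50, 0.7),
(100, 0.6)} with B = 50, m = 20, thresholds 0.30–0.90 step 0.05, and 5
seeds per setting — about half a minute per setting on one CPU. These sizes
are the package's chosen benchmark scale; larger B and m change the Monte
Carlo error, not the structure of the results.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] and symmetrized after `np.corrcoef`
  to remove floating overshoot; the diagonal is set to exactly 1.
- Strict `>` at the threshold, so grid values that coincide with exact
  correlations (as happens with constructed matrices) exclude the tie.
- Module ids are canonical: 1-based, decreasing size, ties by first member
  position — serialized tables are stable across runs.
- `argmax` over the ascending grid implements the smaller-t tie rule exactly.
- Partition agreement is computed from the p × U contingency table, so a
  B = 50, m = 20 profile over 13 thresholds costs seconds, not minutes.

## Known limitations

- The null expectation compares randomizations of the *observed* graph
  only. Where that graph is sparse but nonempty, its degree-preserving
  randomizations are nearly rigid (E[S_null] → 1) while bootstrap resamples
  still vary, so S^Δ is markedly negative on structureless data rather than
  exactly 0. The selection consequence is benign — no threshold looks better
  than the trivial solutions, and the profile shows no spurious positive
  peak (asserted in the tests) — but S^Δ should be read as a selection
  statistic, not as a calibrated effect size.
- Pearson correlation only is exercised; the graph layer accepts any
  precomputed correlation matrix, so rank-based or other dissimilarities
  can be substituted upstream.
- Weighted graphs, overlapping modules, and partial-correlation (GGM)
  estimation of the reference graph are out of scope.
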