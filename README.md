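# netstab

Bootstrap stability estimation for module detection in correlation networks.

## The problem

In systems biology (co-expression, metabolomics, microbiome studies) a
network is often *learned* from data: estimate the p × p Pearson correlation
matrix `C` of the variables from N observations, place an edge between
variables i and j whenever `|C(i, j)| > t`, and partition the resulting
graph into modules with a community-detection algorithm. Two sources of
uncertainty are usually ignored:

1. **Sampling noise.** The graph, and hence the modules, would look
   different had different subjects been sampled.
2. **The threshold t.** It is a free complexity parameter: `t = 0` gives one
   giant module, `t ≥ 1` gives all singletons, and both extremes are
   *perfectly stable* — raw stability alone selects trivial solutions.

`netstab` addresses both with a nonparametric bootstrap. Observations are
resampled with replacement B times; each resample is re-correlated,
re-thresholded at the same t, and re-partitioned with fast-greedy modularity
optimization (CNM). Agreement between two partitions ℳ, ℳ' is measured
node-wise by the Jaccard coefficient of the modules containing node n,

    A(n; ℳ, ℳ') = |ℳ(n) ∩ ℳ'(n)| / |ℳ(n) ∪ ℳ'(n)|,

and averaged: over nodes to compare two partitions, over bootstrap
replicates for **node stability** S_node, over a module's members for
**module stability** S_module, and over everything for the **overall
stability** S_over. For threshold selection, the **unconditional observed
stability** S_obs(t) — the mean pairwise agreement among all B+1 partitions
— is referenced against the expected agreement E[S_null(t)] among partitions
of m degree-preserving randomizations of the observed graph (double-edge
swaps, which keep every node's degree but destroy module structure). The
gap-style statistic

    S^Δ(t) = S_obs(t) − E[S_null(t)]

is maximized over a threshold grid; ties go to the smaller t. The selected
t_opt is the threshold whose modules are most reproducible *beyond what the
graph's density alone explains*.

## Worked example

Simulate 40 observations of 12 variables from a 3-block correlation model
(within-block correlation 0.7, between-block 0.1) and fit:

```python
import numpy as np
from netstab import (BlockModelSpec, ModuleStabilityModel,
                     block_diagonal_correlation, sample_gaussian)

spec = BlockModelSpec(p=12, n_modules=3, alpha=0.7, beta=0.1, N=40)
data = sample_gaussian(block_diagonal_correlation(spec), spec.N, seed=7)

model = ModuleStabilityModel(data)   # or ModuleStabilityModel.from_csv(path)
res = model.fit(thresholds=np.round(np.arange(0.2, 0.81, 0.1), 10),
                B=50, m=20, seed=7)
print(res.summary())
```

```
Module stability profile
================================================================
observations: 40    variables: 12
bootstraps B: 50    null graphs m: 20
----------------------------------------------------------------
     t    S_obs  E[S_null]   S_delta   edges  modules
  0.20   0.5989     0.3277    0.2712      27        3
  0.30   0.8288     0.3264    0.5024      18        3
  0.40   0.9651     0.3313    0.6338      18        3
  0.50   0.9743     0.3222    0.6521      17        3  <- t_opt
  0.60   0.8890     0.3095    0.5795      16        3
  0.70   0.7462     0.4576    0.2886      10        5
  0.80   0.7562     1.0000   -0.2438       1       11
----------------------------------------------------------------
selected t_opt = 0.50: 3 modules, overall stability 0.9868
```

Reading the table: at very low t the dense graph is unstable relative to its
null; at t = 0.8 the graph is nearly edgeless and its null expectation hits
1 (a near-rigid graph randomizes to itself), so S^Δ turns negative. The peak
at t = 0.50 sits inside the true band [β, α) = [0.1, 0.7) and recovers the
three planted blocks exactly. The per-node detail:

```python
print(res.report_.to_frame().head(4).to_string(index=False))
```

```
variable  module  node_stability  module_stability
      V1       1          0.9900          0.984375
      V2       1          0.9675          0.984375
      V3       1          0.9900          0.984375
      V4       1          0.9900          0.984375
```

`res.modules_` holds the partition at t_opt, `res.profile` the full
per-threshold record (with `.plot()`), and `res.save(outdir)` writes the
profile (CSV/JSON), per-threshold stability reports, the module table and
the edge list.

The same pipeline is available from the shell:

```bash
netstab profile --input data.csv --t-min 0.2 --t-max 0.8 --t-step 0.1 \
        --B 50 --null-m 20 --seed 7 --out results/
netstab stability --input data.csv --t 0.5 --B 100 --seed 7 --out results/
netstab simulate --simulate-block 100,10,0.8,0.1,30 --n-seeds 5 --seed 1 \
        --B 50 --null-m 20 --out sweep.csv
```

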