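# synthutil

Validation framework for **broad utility metrics of synthetic tabular health
data**: does a distance between a real dataset and its synthetic imitations
correctly rank competing synthetic-data-generation (SDG) methods by how well
their output supports a real analytic workload?

Synthetic data releases are evaluated with two kinds of utility metrics.
*Narrow* (workload-aware) metrics score the analysis a data user actually
runs — here, logistic-regression prediction of a clinical outcome,
summarized by |AUROC_real − AUROC_syn| and |AUPRC_real − AUPRC_syn|.
*Broad* metrics are distances between the joint distributions of real and
synthetic data, usable before any workload is known.  An analyst choosing
among SDG methods needs broad metrics that are *predictive* of narrow
utility.  `synthutil` implements six broad metrics, the workload metrics,
and the rank-based statistics that test whether each broad metric orders
SDG methods the way the workload does — all of it runnable end-to-end on
simulated data with a known ground-truth ordering.

## The metrics

All six broad metrics are distances (lower = higher utility), computed on a
shared encoding in which the real data defines the standardization and
one-hot layout:

- **MMD** — biased V-statistic of the squared maximum mean discrepancy with
  an RBF kernel, median-heuristic bandwidth.
- **Multivariate Hellinger distance** — Gaussian copulas (normal-scores
  correlations Σ_O, Σ_S) are fitted to each dataset;
  `BC = det(Σ_O)^¼ det(Σ_S)^¼ / det((Σ_O+Σ_S)/2)^½` and `H = √(1 − BC)`,
  bounded in [0, 1].
- **Wasserstein (W₁)** — sliced W₁: the mean univariate W₁ over fixed
  random unit projections of the encoded space (per-feature and exact-OT
  variants available).
- **Cluster analysis measure** — k-means with G clusters on the merged
  data; `U_c = (1/G) Σ_j w_j (n_jO/n_j − c)²` with `c = n_O/(n_O+n_M)`,
  `w_j = n_j/N`.
- **propensityMSE** — a classifier is trained to distinguish real (1) from
  synthetic (0) on the full stack and scored in-sample:
  `mean((p̂ − 0.5)²)`, 0 when indistinguishable, 0.25 at perfect
  separation (equal sizes).
- **predictionMSE** — the same score computed on a held-out third of the
  stack (train/holdout separation).

The ranking test: for each metric, the three SDG methods are grouped per
dataset into **H**igh / **M**iddle / **L**ow predicted utility; each group
member is replaced by its workload difference and ranked within the
dataset.  With column rank sums R₁, R₂, R₃ over (H, M, L), the **Page
statistic** `L = R₁ + 2R₂ + 3R₃` is large when workload error grows from H
to L; significance comes from the exact permutation null (computed by
dynamic programming), with a Bonferroni adjustment across the metrics
tested.  A consensus ranking minimizing the total **Spearman footrule**
distance to the per-metric rankings (over all 3! candidates; predictionMSE
excluded as near-duplicate of propensityMSE) is tested the same way.

Because real multi-dataset benchmarks cannot be redistributed, the package
ships a simulator of heterogeneous health-like datasets (Gaussian-copula
predictors, logistic outcome) and three stand-in SDG methods with a
**fidelity ladder known by construction**: Gaussian-copula synthesis (top),
sequential decision-tree synthesis (middle), independent marginal
resampling (bottom).

## Worked example

```sh
python examples/02_synthesize_and_score.py
```

```text
method                       mmd       hellinger     wasserstein         cluster  propensity_mse  prediction_mse
copula                    0.0004          0.1307          0.0387          0.0001          0.0098          0.0153
sequential_tree           0.0008          0.2047          0.0392          0.0002          0.0211          0.0273
marginal                  0.0018          0.3570          0.0524          0.0004          0.0554          0.0615
```

Every metric increases down the rows: each one, on this dataset, orders the
three synthesizers exactly as constructed.  The narrow metrics agree
(`examples/03_workload_fidelity.py`): the real-data model reaches AUROC
0.777 and the copula's synthetic model 0.735 (difference 0.042), while
marginal resampling severs outcome from predictors and falls to chance
(0.513, difference 0.264).

Running the ranking stage over 10 simulated datasets × 3 methods × 5
replicates (`examples/04_page_test_and_aggregate.py`) gives, per metric and
workload, a Page L between 138 and 140 against the maximum 14n = 140 and
exact p-values below 10⁻⁵ — every metric, and the footrule aggregate,
ranks the methods significantly at the Bonferroni-adjusted α = .05/6, and
the median AUROC difference rises monotonically across the Hellinger
groups (H 0.025, M 0.107, L 0.310).

A thin CLI wraps the same flow:

```sh
synthutil simulate --seed 1 --n-datasets 5 --out data/
synthutil run --seed 1 --out results/
synthutil plot --cells results/cells.csv --metric hellinger --out results/
```

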