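# Methods

## What is being validated, and how

A broad utility metric is useful to an analyst only if it ranks competing
synthetic-data generators the same way a downstream workload would.  The
framework tests this as a trend hypothesis.  For one utility metric and a
collection of datasets:

1. For each dataset, each of three generators is fitted to the real data
   and sampled `replicates` times (default 5; larger replicate counts
   mainly tighten the cell means).  The six broad metrics and the two
   workload differences (|ΔAUROC|, |ΔAUPRC| of 3-fold CV logistic
   regression) are computed per replicate and averaged, giving one value
   per (dataset, method) cell.  Averaging over replicates is what makes
   these *model-specific* utilities: a single synthetic draw is too noisy
   to characterize a generator.
2. The three methods are assigned to H / M / L groups per dataset by the
   metric's cell means (H = smallest distance).  Each group member is
   replaced by its workload difference, and the three values are ranked
   within the dataset (smallest difference → rank 1).
3. With column rank sums R₁, R₂, R₃ over (H, M, L), the Page statistic
   L = R₁ + 2R₂ + 3R₃ measures the monotone trend.  Under the null that
   each row's ranks are an independent uniform permutation of (1, 2, 3),
   the distribution of L is the n-fold convolution of the per-row
   distribution {10: 1/6, 11: 2/6, 13: 2/6, 14: 1/6}; the implementation
   convolves exactly over integers, so p-values are exact rationals.
   The null mean is 12n and the range [10n, 14n].  Decisions use a
   Bonferroni adjustment with m = number of utility metrics tested (6).
4. A consensus ranking per dataset minimizes the summed Spearman footrule
   distance to the per-metric rankings over all 3! candidates
   (predictionMSE excluded by default as strongly related to
   propensityMSE; a leave-one-out post-hoc drops each aggregated metric in
   turn).  Cost ties are broken by majority pairwise preference, then
   lexicographically, and flagged.

Rows with tied workload differences get mid-ranks; the exact null then no
longer applies, so the test falls back to a row-permutation Monte-Carlo
p-value (flagged as non-exact).

## The simulated study population

Real multi-dataset benchmarks in this area cannot be redistributed, so the
generator module *is* the study population.  `random_real_spec` draws
heterogeneous dataset recipes: 500–2,000 rows, 2–5 continuous and 1–3
categorical predictors (2–4 levels), a random latent correlation matrix
shrunk toward the identity by a weight in [0.4, 0.8] (so dependence is
non-trivial but variable), and a binary outcome from a logistic link whose
linear predictor has SD ≈ 1.5, giving real-data AUROC around 0.8.
`simulate_real` realizes a recipe as a Gaussian copula: a latent
multivariate normal is pushed through monotone transforms per continuous
column (affine, exponential, affine — cycled, so scales and skewness vary)
and sliced at equal-probability quantiles for categoricals.  With K > 2
outcome levels the class-k logit is s_k·(xᵀβ) with s_k equally spaced in
[−1, 1] — the ordinary logistic link at K = 2, and β = 0 always yields an
outcome independent of the predictors.

Categorical outcome coefficients are drawn as an ordered ramp over levels
(a single slope times a linear level trend).  Free per-level coefficients
would create non-monotone, level-specific outcome dependence that no
Gaussian copula can represent — which would silently falsify the premise
that the copula synthesizer is the highest-fidelity stand-in.  Ordered
level effects (dose-, stage- or age-group-like) keep that premise true and
are the common case in health data.

What the simulator does **not** emulate: missing data, measurement error,
rare levels and extreme class imbalance, heavy-tailed outliers beyond the
lognormal transform, non-monotone predictor-outcome relations, and
longitudinal structure.  Passing tests show the framework detects utility
differences under clean, monotone, copula-style dependence; they do not
certify behavior on data violating those assumptions.

## The stand-in generators and the fidelity ladder

Training the generative models used in practice (GANs, differentially
private Bayesian networks) is out of scope; what the validation needs is
*methods of genuinely different utility whose order is known*.  Three
cheap synthesizers provide that ladder:

- **copula** (top): per-column normal scores Φ⁻¹(rank/(n+1)) with
  mid-ranks for ties (ordinal codes for categoricals), their Pearson
  correlation de-attenuated by closed-form discretization factors (the
  polyserial-style moment correction: for a categorical with latent bins,
  the measured score correlation is the latent one shrunk by
  a = E[g(z)z]/sd(g(z)), computable from the level frequencies), clipped
  and ridge-projected to positive-definite.  Sampling draws a latent
  normal with that correlation and inverts each empirical marginal.
  Without the de-attenuation, fitting on discretized scores and then
  re-discretizing at sampling shrinks categorical dependence twice, and
  the copula loses its by-construction top rank.
- **sequential_tree** (middle): sequential CART synthesis — columns in
  metadata order, outcome last; each column is drawn by fitting a
  decision tree (classification for categoricals, regression for
  continuous) on the previously synthesized columns and resampling
  observed real values within the predicted leaf.  `min_samples_leaf`
  positions this method on the ladder: very small leaves quasi-memorize
  the real sample (the synthetic draw then tracks the real one more
  closely than an independent copula redraw can, inverting the ladder),
  very large leaves degrade toward marginal resampling.  The default of
  100 sits robustly in the middle at the simulated sizes.
- **marginal** (bottom): independent with-replacement resampling of each
  column — marginals exact, dependence destroyed.

Synthetic datasets match the real row count by default because the
distinguishability metrics center at 0.5 only for equal-size stacks.
Every replicate's seed is hash-derived from (base seed, dataset, method,
replicate), so any cell of an experiment is reproducible in isolation;
"fitting" is deterministic in the real data, so re-fitting per replicate
equals fitting once.

## Metric implementation choices

One shared encoding serves all metrics: continuous features centered and
scaled by the real data's mean/SD (zero-variance guard: scale 1),
categoricals one-hot over declared levels; the real dataset always defines
the space and a synthetic level outside it is an error.  Broad metrics see
the outcome column too (they compare full joints); workload models see
predictors only.

- **MMD**: biased V-statistic (nonnegative by construction), RBF kernel,
  median-heuristic bandwidth on pooled pairwise distances; an all-identical
  pool returns 0 with a warning.
- **Hellinger**: copulas are fitted on a full-rank reduction of the
  encoding (one level dropped per one-hot block).  A complete block sums
  to 1 per row, making the score correlation exactly singular and the
  determinant-based Bhattacharyya coefficient meaningless — empirically
  the distance saturates near 1 for every method.  Correlations are
  ridge-escalated (εI from 1e-8, rescaled to unit diagonal) until a
  Cholesky factorization exists; log-determinants come from that
  factorization; H is clamped to [0, 1].  An ordinal-code variant of the
  copula input is available by config.
- **Wasserstein**: default is sliced W₁ — the mean of closed-form
  univariate W₁ over 64 random unit projections drawn once from a fixed
  seed (deterministic given inputs).  A purely per-feature W₁ compares
  marginals only and is provably blind to dependence differences (it
  cannot separate marginal resampling from the copula); it remains
  available as `per_feature`, and an exact uniform-weight OT variant
  (Hungarian assignment) as `multivariate_ot` for small n.
- **Cluster measure**: k-means, G = 20 by default (capped at the stack
  size), 10 restarts, seeded; proportional weights w_j = n_j/N make U_c a
  weighted variance of cluster mixing.  Empty clusters simply drop out of
  the sum with G counting non-empty ones.
- **propensityMSE / predictionMSE**: the default discriminator is L2
  logistic regression on a degree-2 polynomial expansion of the encoded
  features (standardized).  Main effects alone cannot detect dependence
  destruction — a marginal resample preserves every feature mean — so a
  first-order propensity model would validate nothing; second-order terms
  are the usual specification in the pMSE literature.  predictionMSE uses
  a stratified 2/3 train / 1/3 holdout split, seeded.  Plain-logistic and
  gradient-boosting discriminators are config switches, as is any object
  with a fit/predict_proba contract.
- **Workload**: stratified 3-fold CV (folds reduced with a warning if an
  outcome level is rarer than the fold count), L2 logistic regression
  (C = 100), AUROC/AUPRC on pooled out-of-fold predictions.  The binary
  positive class is the second declared outcome level — a schema-fixed
  rule so real and synthetic evaluations agree.  Multicategory outcomes
  use the mean of pairwise two-class AUROCs (each pair averaged over both
  orientations, Hand-and-Till style) and macro-averaged one-vs-rest
  average precision.  Synthetic models are evaluated by CV within the
  synthetic data, in parallel with the real fit, both in the real data's
  predictor encoding and with the same fold seed.

## Numerical and procedural details

- Entropy (descriptive only): Shannon entropy base 2 per column, equal-
  width binning into ⌈√n⌉ bins for continuous columns; constant columns
  contribute 0.
- Missing values are rejected at read time; the framework assumes complete
  data, and silent imputation would contaminate metric comparisons.
- Categorical levels are fixed at read time (sorted lexicographically when
  inferred), making one-hot layouts reproducible.
- CSV round-trips are exact: floats are written with `%.17g` and parsed
  with correctly-rounded conversion.
- Ties anywhere in grouping or ranking are broken deterministically
  (lexicographic) and flagged; tied rank rows route the Page test to the
  Monte-Carlo fallback.
- Experiment scales: the default profile is 10 datasets × 3 methods × 5
  replicates at 500 rows; the full profile used by the reproduction
  script and the end-to-end tests is 30 datasets at 500–2,000 rows.

## Known limitations

- The ladder's middle rung depends on the tree leaf size relative to n;
  at sizes far outside 500–2,000 the default of 100 may need revisiting.
- The Hellinger metric sees only the copula (rank-correlation) structure
  of the joints; generators that distort marginals while preserving ranks
  are invisible to it (the other metrics cover that direction).
- The exact Page null assumes tie-free rows and 3 columns; the general-k
  table is not provided.
- Aggregate-ranking tie-breaking by majority preference is a heuristic;
  with many cost ties (e.g., near-identical methods) the flagged result
  should be inspected rather than trusted blindly.
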