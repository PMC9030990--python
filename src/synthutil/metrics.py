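"""Broad utility metrics: distances between real and synthetic datasets.

All six metrics are distance-type — lower means higher utility — and all
are computed on one shared encoding in which the real dataset defines the
standardization and one-hot layout:

* squared maximum mean discrepancy with an RBF kernel (``mmd_rbf``),
* multivariate Hellinger distance between Gaussian copulas fitted to each
  dataset (``fit_copula`` + ``hellinger_gaussian``),
* mean per-feature W1 Wasserstein distance (``wasserstein_distance``),
* the cluster-analysis disparity measure U_c (``cluster_utility``),
* propensityMSE — mean squared deviation from 0.5 of an in-sample
  real-vs-synthetic classifier's probabilities (``propensity_mse``),
* predictionMSE — the same deviation measured on a holdout split
  (``prediction_mse``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import norm, rankdata
from scipy.stats import wasserstein_distance as _w1
from sklearn.cluster import KMeans
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .tabular import EncodedMatrix, TabularDataset, encode, fit_standardization

__all__ = [
    "METRIC_NAMES",
    "UtilityScore",
    "CopulaFit",
    "MetricConfig",
    "mmd_rbf",
    "fit_copula",
    "hellinger_gaussian",
    "wasserstein_distance",
    "cluster_utility",
    "propensity_mse",
    "prediction_mse",
    "compute_all_metrics",
]

METRIC_NAMES = ("mmd", "hellinger", "wasserstein", "cluster",
                "propensity_mse", "prediction_mse")


@dataclass(frozen=True)
class UtilityScore:
    """One metric value for one (dataset, method, replicate) cell."""

    metric_name: str
    value: float
    dataset_name: str = ""
    method_name: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric_name!r}")
        if self.value < 0:
            raise ValueError("utility distances are nonnegative")


@dataclass
class CopulaFit:
    """Normal-scores correlation matrix of an encoded dataset."""

    correlation: np.ndarray

    @property
    def d(self) -> int:
        return self.correlation.shape[0]


@dataclass
class MetricConfig:
    """Tunable knobs shared by one experiment run.

    ``classifier`` may be "logistic" or any object with sklearn's
    fit/predict_proba contract (used directly — handy for stubbing).
    """

    mmd_bandwidth: float | str = "median"
    cluster_g: int = 20
    classifier: object = "logistic2"  # "logistic", "logistic2", "gbm" or estimator
    lr_c: float = 100.0
    prediction_test_fraction: float = 1.0 / 3.0
    wasserstein_variant: str = "sliced"  # "per_feature" or "multivariate_ot"
    wasserstein_projections: int = 64
    copula_categorical: str = "onehot"  # or "ordinal"
    seed: int = 0


# ----------------------------------------------------------------------
# MMD
# ----------------------------------------------------------------------

def mmd_rbf(real_enc: EncodedMatrix, syn_enc: EncodedMatrix,
            bandwidth: float | str = "median") -> float:
    """Biased (V-statistic) squared MMD with kernel exp(-||x-y||^2 / 2s^2).

    The bandwidth ``s`` is the median of the pooled pairwise Euclidean
    distances when "median" is requested.  The V-statistic is nonnegative
    by construction.  If every point in both samples coincides the median
    distance is zero; the two samples are then identical point masses and
    0 is returned with a warning.
    """
    X, Y = real_enc.matrix, syn_enc.matrix
    if X.shape[1] != Y.shape[1]:
        raise ValueError("encoded dimension mismatch")
    if len(X) < 1 or len(Y) < 1:
        raise ValueError("need at least one row per sample")
    dxx = cdist(X, X, "sqeuclidean")
    dyy = cdist(Y, Y, "sqeuclidean")
    dxy = cdist(X, Y, "sqeuclidean")
    if bandwidth == "median":
        pooled = np.concatenate([
            dxx[np.triu_indices(len(X), k=1)],
            dyy[np.triu_indices(len(Y), k=1)],
            dxy.ravel(),
        ])
        med = float(np.median(np.sqrt(pooled))) if pooled.size else 0.0
        if med == 0.0:
            warnings.warn("all pooled pairwise distances are zero; MMD = 0")
            return 0.0
        s2 = med ** 2
    else:
        s2 = float(bandwidth) ** 2
    kxx = np.exp(-dxx / (2 * s2)).mean()
    kyy = np.exp(-dyy / (2 * s2)).mean()
    kxy = np.exp(-dxy / (2 * s2)).mean()
    return float(max(kxx + kyy - 2 * kxy, 0.0))


# ----------------------------------------------------------------------
# Gaussian-copula Hellinger
# ----------------------------------------------------------------------

def _full_rank_columns(enc: EncodedMatrix) -> np.ndarray:
    """Column indices keeping continuous features and all but the last
    level of each one-hot block (the block sums to 1 per row, so the full
    block is rank-deficient and would degenerate the copula determinants)."""
    fmap = enc.feature_map
    keep = []
    for j, (col, lev) in enumerate(fmap):
        if lev is None:
            keep.append(j)
        else:
            last_of_block = j + 1 == len(fmap) or fmap[j + 1][0] != col
            if not last_of_block:
                keep.append(j)
    return np.asarray(keep, dtype=int)


def fit_copula(enc: EncodedMatrix) -> CopulaFit:
    """Gaussian copula of an encoded sample: normal scores + correlation.

    Each feature is rank-transformed with mid-ranks for ties and mapped
    through Phi^-1(rank/(n+1)); the Pearson correlation of the score
    matrix is ridge-regularized (escalating eps*I, rescaled to unit
    diagonal) until positive-definite so log-determinants exist.  A
    constant feature keeps its unit diagonal and zero correlations.
    One-hot encodings are reduced to a full-rank representation first
    (one level per block dropped); real and synthetic fits share the same
    reference layout, so their reduced spaces coincide.
    """
    if isinstance(enc, EncodedMatrix):
        X = enc.matrix[:, _full_rank_columns(enc)]
    else:
        X = np.asarray(enc, dtype=float)
    n, d = X.shape
    scores = np.empty_like(X, dtype=float)
    for j in range(d):
        scores[:, j] = norm.ppf(rankdata(X[:, j], method="average") / (n + 1))
    sds = scores.std(axis=0)
    R = np.eye(d)
    ok = sds > 0
    if ok.sum() >= 2:
        R[np.ix_(ok, ok)] = np.corrcoef(scores[:, ok], rowvar=False)
    eps = 1e-8
    while True:
        try:
            np.linalg.cholesky(R)
            break
        except np.linalg.LinAlgError:
            R = R + eps * np.eye(d)
            dinv = 1.0 / np.sqrt(np.diag(R))
            R = R * np.outer(dinv, dinv)
            eps *= 10
    return CopulaFit(correlation=R)


def hellinger_gaussian(fit_real: CopulaFit, fit_syn: CopulaFit) -> float:
    """Hellinger distance between two zero-mean Gaussians, in [0, 1].

    Uses the Bhattacharyya coefficient
    ``BC = det(S1)^(1/4) det(S2)^(1/4) / det((S1+S2)/2)^(1/2)`` computed in
    log space via Cholesky factorizations, and returns ``sqrt(1 - BC)``
    clamped against floating-point drift.
    """
    if fit_real.d != fit_syn.d:
        raise ValueError("copula dimension mismatch")
    s1, s2 = fit_real.correlation, fit_syn.correlation
    avg = 0.5 * (s1 + s2)

    def _logdet(m: np.ndarray) -> float:
        L = np.linalg.cholesky(m)
        return 2.0 * float(np.sum(np.log(np.diag(L))))

    log_bc = 0.25 * _logdet(s1) + 0.25 * _logdet(s2) - 0.5 * _logdet(avg)
    bc = min(np.exp(log_bc), 1.0)
    return float(np.sqrt(max(1.0 - bc, 0.0)))


# ----------------------------------------------------------------------
# Wasserstein
# ----------------------------------------------------------------------

def wasserstein_distance(real_enc: EncodedMatrix, syn_enc: EncodedMatrix,
                         variant: str = "sliced", n_projections: int = 64) -> float:
    """W1 distance between the empirical encodings.

    The default "sliced" variant averages the closed-form univariate W1
    over ``n_projections`` fixed random unit directions of the shared
    standardized space — a standard multivariate W1 estimator that, unlike
    a purely marginal comparison, responds to differences in the joint
    (dependence) structure.  The projection directions are derived from a
    fixed seed, so the estimate is deterministic given the inputs.

    ``variant="per_feature"`` is the mean of per-feature univariate W1
    (area between sorted quantile functions) — it compares marginals only.
    ``variant="multivariate_ot"`` solves the exact uniform-weight optimal
    transport (Hungarian assignment on Euclidean cost); it requires equal
    sample sizes and is practical only at small n.
    """
    X, Y = real_enc.matrix, syn_enc.matrix
    if X.shape[1] != Y.shape[1]:
        raise ValueError("encoded dimension mismatch")
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("empty sample")
    if variant == "per_feature":
        return float(np.mean([_w1(X[:, j], Y[:, j]) for j in range(X.shape[1])]))
    if variant == "sliced":
        d = X.shape[1]
        if d == 1:
            return float(_w1(X[:, 0], Y[:, 0]))
        rng = np.random.default_rng(12345)  # fixed: estimator is deterministic
        U = rng.standard_normal((d, n_projections))
        U /= np.linalg.norm(U, axis=0, keepdims=True)
        px, py = X @ U, Y @ U
        return float(np.mean([_w1(px[:, k], py[:, k])
                              for k in range(n_projections)]))
    if variant == "multivariate_ot":
        if len(X) != len(Y):
            raise ValueError("multivariate OT variant needs equal sizes")
        cost = cdist(X, Y, "euclidean")
        r, c = linear_sum_assignment(cost)
        return float(cost[r, c].mean())
    raise ValueError(f"unknown variant {variant!r}")


# ----------------------------------------------------------------------
# Cluster disparity
# ----------------------------------------------------------------------

def cluster_utility(real_enc: EncodedMatrix, syn_enc: EncodedMatrix,
                    g: int = 20, seed: int = 0,
                    labels: np.ndarray | None = None) -> float:
    """Cluster-analysis disparity U_c on the stacked real+synthetic rows.

    k-means with ``g`` clusters (10 restarts, seeded) partitions the
    merged data; with ``c = n_O / (n_O + n_M)`` the overall real share and
    ``w_j = n_j / N`` proportional weights,

        U_c = (1/G) * sum_j w_j * (n_jO / n_j - c)^2.

    Perfect mixing gives 0; fully separated stacks give the maximum for
    the realized cluster sizes.  ``labels`` overrides the k-means
    assignment (used for closed-form checks).  If k-means returns fewer
    than ``g`` non-empty clusters the sum simply runs over the non-empty
    ones, G counting only those.
    """
    X, Y = real_enc.matrix, syn_enc.matrix
    n_o, n_m = len(X), len(Y)
    stacked = np.vstack([X, Y])
    if labels is None:
        if g < 2 or g > len(stacked):
            raise ValueError("need 2 <= G <= total rows")
        km = KMeans(n_clusters=g, n_init=10, random_state=seed)
        labels = km.fit_predict(stacked)
    labels = np.asarray(labels)
    is_real = np.arange(len(stacked)) < n_o
    c = n_o / (n_o + n_m)
    total = n_o + n_m
    uniq = np.unique(labels)
    g_eff = len(uniq)
    u = 0.0
    for j in uniq:
        mask = labels == j
        n_j = int(mask.sum())
        n_jo = int((mask & is_real).sum())
        w_j = n_j / total
        u += w_j * (n_jo / n_j - c) ** 2
    return float(u / g_eff)


# ----------------------------------------------------------------------
# Distinguishability
# ----------------------------------------------------------------------

def _make_classifier(config: MetricConfig | object):
    """Build the real-vs-synthetic discriminator.

    "logistic2" (default) is L2 logistic regression on a degree-2
    polynomial expansion of the encoded features: main effects alone are
    blind to pure dependence differences (a marginal resample preserves
    every feature mean), while second-order terms expose them — the usual
    propensity-model specification in the pMSE literature.  "logistic" is
    main effects only; "gbm" is gradient-boosted trees; any object with a
    fit/predict_proba contract is used as-is.
    """
    clf = getattr(config, "classifier", config)
    if isinstance(clf, str):
        c = getattr(config, "lr_c", 100.0)
        if clf == "logistic":
            return LogisticRegression(C=c, max_iter=2000)
        if clf == "logistic2":
            return Pipeline([
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(C=c, max_iter=2000)),
            ])
        if clf == "gbm":
            return GradientBoostingClassifier(random_state=0)
        raise ValueError(f"unknown classifier {clf!r}")
    return clf


def _stack(real_enc: EncodedMatrix, syn_enc: EncodedMatrix):
    if real_enc.n_rows != syn_enc.n_rows:
        raise ValueError("distinguishability metrics assume equal sample sizes")
    X = np.vstack([real_enc.matrix, syn_enc.matrix])
    y = np.concatenate([np.ones(real_enc.n_rows), np.zeros(syn_enc.n_rows)])
    return X, y


def propensity_mse(real_enc: EncodedMatrix, syn_enc: EncodedMatrix,
                   classifier_config: MetricConfig | object | None = None) -> float:
    """In-sample propensity MSE: train real-vs-synthetic classifier on the
    full stack, score the same stack, return mean((p_hat - 0.5)^2).

    0 for indistinguishable stacks, 0.25 when a calibrated classifier
    separates them perfectly (equal sizes assumed and enforced)."""
    config = classifier_config if classifier_config is not None else MetricConfig()
    X, y = _stack(real_enc, syn_enc)
    clf = _make_classifier(config)
    clf.fit(X, y)
    p = clf.predict_proba(X)[:, 1]
    return float(np.mean((p - 0.5) ** 2))


def prediction_mse(real_enc: EncodedMatrix, syn_enc: EncodedMatrix,
                   classifier_config: MetricConfig | object | None = None,
                   split_seed: int = 0) -> float:
    """Holdout propensity MSE: stratified 2/3 train / 1/3 test split of the
    stack; mean((p_hat - 0.5)^2) over holdout predictions only."""
    config = classifier_config if classifier_config is not None else MetricConfig()
    X, y = _stack(real_enc, syn_enc)
    frac = getattr(config, "prediction_test_fraction", 1.0 / 3.0)
    X_tr, X_te, y_tr, _ = train_test_split(
        X, y, test_size=frac, stratify=y, random_state=split_seed
    )
    clf = _make_classifier(config)
    clf.fit(X_tr, y_tr)
    p = clf.predict_proba(X_te)[:, 1]
    return float(np.mean((p - 0.5) ** 2))


# ----------------------------------------------------------------------
# Batch driver
# ----------------------------------------------------------------------

def _ordinal_matrix(ds: TabularDataset) -> np.ndarray:
    """Columns as raw numerics, categoricals by ordinal level code — the
    alternative copula input when one-hot rank transforms are not wanted."""
    cols = []
    for c in ds.columns:
        if c.kind == "continuous":
            cols.append(ds.values[c.name].to_numpy(dtype=float))
        else:
            code = {lev: i for i, lev in enumerate(c.levels)}
            cols.append(ds.values[c.name].map(code).to_numpy(dtype=float))
    return np.column_stack(cols)


def compute_all_metrics(real: TabularDataset, syn: TabularDataset,
                        config: MetricConfig | None = None,
                        dataset_name: str | None = None,
                        method_name: str = "", replicate_index: int = 0,
                        real_enc: EncodedMatrix | None = None,
                        real_copula: CopulaFit | None = None) -> list[UtilityScore]:
    """Compute all six metrics for one (real, synthetic) pair.

    Both datasets are realized in the real dataset's encoding space
    (including the outcome column, since broad metrics compare the full
    joint distribution).  Precomputed ``real_enc``/``real_copula`` can be
    passed when the same real dataset is scored against many replicates.
    """
    config = config or MetricConfig()
    if not real.same_schema(syn):
        raise ValueError("real and synthetic schemas differ")
    if real_enc is None:
        real_enc = encode(real, include_outcome=True)
    syn_enc = encode(syn, reference=real_enc.standardization)
    if real_copula is None:
        real_copula = fit_copula(real_enc)
    name = dataset_name if dataset_name is not None else real.name
    seed = getattr(config, "seed", 0)
    g = min(config.cluster_g, real_enc.n_rows + syn_enc.n_rows)
    if config.copula_categorical == "ordinal":
        real_cop = fit_copula(_ordinal_matrix(real))
        syn_cop = fit_copula(_ordinal_matrix(syn))
    else:
        real_cop = real_copula
        syn_cop = fit_copula(syn_enc)
    values = {
        "mmd": mmd_rbf(real_enc, syn_enc, config.mmd_bandwidth),
        "hellinger": hellinger_gaussian(real_cop, syn_cop),
        "wasserstein": wasserstein_distance(real_enc, syn_enc,
                                            config.wasserstein_variant),
        "cluster": cluster_utility(real_enc, syn_enc, g=g,
                                   seed=seed + replicate_index),
        "propensity_mse": propensity_mse(real_enc, syn_enc, config),
        "prediction_mse": prediction_mse(real_enc, syn_enc, config,
                                         split_seed=seed + replicate_index),
    }
    return [
        UtilityScore(metric_name=m, value=values[m], dataset_name=name,
                     method_name=method_name, replicate_index=replicate_index)
        for m in METRIC_NAMES
    ]
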