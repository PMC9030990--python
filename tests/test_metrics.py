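import numpy as np
import pytest

from synthutil import (
    CopulaFit,
    MetricConfig,
    UtilityScore,
    cluster_utility,
    compute_all_metrics,
    encode,
    fit_copula,
    hellinger_gaussian,
    mmd_rbf,
    prediction_mse,
    propensity_mse,
    wasserstein_distance,
)
from synthutil.tabular import EncodedMatrix, Standardization


def _enc(mat: np.ndarray) -> EncodedMatrix:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    d = mat.shape[1]
    fmap = tuple((f"f{j}", None) for j in range(d))
    std = Standardization(columns=(), feature_map=fmap,
                          center=(0.0,) * d, scale=(1.0,) * d)
    return EncodedMatrix(matrix=mat, feature_map=fmap, standardization=std)


class StubClassifier:
    """predict_proba returns fixed positive-class probabilities in order."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = self.probs[: len(X)]
        return np.column_stack([1 - p, p])


class TestMMD:
    def test_identical_samples_give_zero(self):
        x = _enc(np.random.default_rng(0).normal(size=(30, 3)))
        assert mmd_rbf(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_kernel_arithmetic(self):
        # single points at distance sigma*sqrt(2): MMD^2 = 2(1 - e^-1)
        sigma = 1.7
        x = _enc([[0.0]])
        y = _enc([[sigma * np.sqrt(2.0)]])
        expected = 2.0 * (1.0 - np.exp(-1.0))
        assert mmd_rbf(x, y, bandwidth=sigma) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_and_symmetric(self):
        rng = np.random.default_rng(1)
        x, y = _enc(rng.normal(size=(40, 4))), _enc(rng.normal(1.0, 2.0, size=(25, 4)))
        v = mmd_rbf(x, y)
        assert v >= 0.0
        assert mmd_rbf(y, x) == pytest.approx(v)

    def test_degenerate_identical_point_masses_warn_and_return_zero(self):
        x = _enc(np.zeros((5, 2)))
        with pytest.warns(UserWarning):
            assert mmd_rbf(x, x) == 0.0


class TestCopulaFit:
    def test_independent_features_have_small_offdiagonals(self):
        rng = np.random.default_rng(2)
        fit = fit_copula(_enc(rng.normal(size=(4000, 3))))
        off = fit.correlation[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_recovers_known_correlation(self):
        rng = np.random.default_rng(3)
        rho = 0.9
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
        fit = fit_copula(_enc(z))
        assert fit.correlation[0, 1] == pytest.approx(rho, abs=0.03)

    def test_constant_feature_keeps_unit_diagonal_zero_correlation(self):
        rng = np.random.default_rng(4)
        m = np.column_stack([rng.normal(size=100), np.full(100, 7.0)])
        fit = fit_copula(_enc(m))
        assert fit.correlation[1, 1] == 1.0
        assert fit.correlation[0, 1] == 0.0
        np.linalg.cholesky(fit.correlation)

    def test_one_hot_blocks_enter_full_rank(self, sim_dataset):
        enc = encode(sim_dataset)
        fit = fit_copula(enc)
        n_onehot = sum(1 for _, lev in enc.feature_map if lev is not None)
        n_blocks = len({c for c, lev in enc.feature_map if lev is not None})
        assert fit.d == enc.d - n_blocks  # one level dropped per block
        np.linalg.cholesky(fit.correlation)


class TestHellinger:
    def test_identical_covariances_give_zero(self):
        s = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert hellinger_gaussian(CopulaFit(s), CopulaFit(s)) == 0.0

    def test_closed_form_two_dimensional_example(self):
        s1 = np.eye(2)
        s2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        bc = 0.75**0.25 / 0.9375**0.5
        expected = np.sqrt(1 - bc)
        assert hellinger_gaussian(CopulaFit(s1), CopulaFit(s2)) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.1972, abs=1e-4)

    def test_degenerate_limit_approaches_one(self):
        s1 = np.eye(2)
        s2 = np.array([[1.0, 1 - 1e-9], [1 - 1e-9, 1.0]])
        assert hellinger_gaussian(CopulaFit(s1), CopulaFit(s2)) > 0.99

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            r1, r2 = rng.uniform(-0.9, 0.9, size=2)
            f1 = CopulaFit(np.array([[1, r1], [r1, 1.0]]))
            f2 = CopulaFit(np.array([[1, r2], [r2, 1.0]]))
            h = hellinger_gaussian(f1, f2)
            assert 0.0 <= h <= 1.0
            assert h == pytest.approx(hellinger_gaussian(f2, f1))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hellinger_gaussian(CopulaFit(np.eye(2)), CopulaFit(np.eye(3)))


class TestWasserstein:
    def test_identical_samples_give_zero(self):
        x = _enc(np.random.default_rng(6).normal(size=(20, 2)))
        assert wasserstein_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "real, syn, expected",
        [
            ([[0.0]], [[3.0]], 3.0),                 # Diracs: |delta|
            ([[0.0], [1.0]], [[0.0], [3.0]], 1.0),   # quantile integral (0+2)/2
        ],
    )
    def test_per_feature_closed_form(self, real, syn, expected):
        assert wasserstein_distance(_enc(real), _enc(syn),
                                    variant="per_feature") == pytest.approx(expected)

    def test_sliced_detects_pure_dependence_difference(self):
        # same standard-normal marginals, opposite dependence
        rng = np.random.default_rng(7)
        z = rng.normal(size=4000)
        real = _enc(np.column_stack([z, z]))
        syn = _enc(np.column_stack([z, rng.normal(size=4000)]))
        assert wasserstein_distance(real, syn, variant="per_feature") < 0.05
        assert wasserstein_distance(real, syn, variant="sliced") > 0.1

    def test_multivariate_ot_matches_sorted_transport_in_1d(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(50, 1)), rng.normal(size=(50, 1))
        exact = wasserstein_distance(_enc(a), _enc(b), variant="multivariate_ot")
        closed = wasserstein_distance(_enc(a), _enc(b), variant="per_feature")
        assert exact == pytest.approx(closed, abs=1e-9)


class TestClusterUtility:
    def test_perfectly_mixed_clusters_give_zero(self):
        real = _enc(np.zeros((4, 1)))
        syn = _enc(np.zeros((4, 1)))
        labels = np.array([0, 0, 1, 1, 0, 0, 1, 1])  # each cluster half real
        assert cluster_utility(real, syn, labels=labels) == 0.0

    def test_fully_separated_eight_row_stack(self):
        # G=2, c=0.5, w_j=0.5, each cluster pure:
        # U_c = (1/2)(0.5*0.25 + 0.5*0.25) = 0.125 by direct arithmetic
        real = _enc(np.zeros((4, 1)))
        syn = _enc(np.ones((4, 1)) * 9)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert cluster_utility(real, syn, labels=labels) == pytest.approx(0.125)

    def test_copy_of_real_scores_near_zero(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(200, 3))
        v = cluster_utility(_enc(m), _enc(m.copy()), g=5, seed=0)
        assert v < 0.005


class TestDistinguishability:
    def test_propensity_stub_probabilities(self):
        real, syn = _enc(np.zeros((2, 1))), _enc(np.zeros((2, 1)))
        stub = StubClassifier([0.6, 0.6, 0.4, 0.4])
        assert propensity_mse(real, syn, stub) == pytest.approx(0.01, abs=1e-15)

    def test_propensity_constant_half_is_zero_and_oracle_is_quarter(self):
        real, syn = _enc(np.zeros((4, 1))), _enc(np.zeros((4, 1)))
        assert propensity_mse(real, syn, StubClassifier([0.5] * 8)) == 0.0
        oracle = StubClassifier([1.0] * 4 + [0.0] * 4)
        assert propensity_mse(real, syn, oracle) == 0.25

    def test_prediction_stub_holdout_probabilities(self):
        real, syn = _enc(np.zeros((3, 1))), _enc(np.zeros((3, 1)))
        # 6-row stack, 1/3 holdout -> 2 rows scored at 0.9 and 0.1
        stub = StubClassifier([0.9, 0.1])
        assert prediction_mse(real, syn, stub, split_seed=0) == pytest.approx(0.16)

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError):
            propensity_mse(_enc(np.zeros((3, 1))), _enc(np.zeros((2, 1))))

    def test_separable_stacks_score_high(self):
        rng = np.random.default_rng(10)
        real = _enc(rng.normal(0.0, 0.1, size=(60, 2)))
        syn = _enc(rng.normal(5.0, 0.1, size=(60, 2)))
        assert propensity_mse(real, syn) > 0.2
        assert prediction_mse(real, syn, split_seed=1) > 0.2


class TestComputeAll:
    def test_copy_of_real_minimizes_every_metric(self, sim_dataset):
        scores = compute_all_metrics(sim_dataset, sim_dataset.copy())
        by_name = {s.metric_name: s.value for s in scores}
        assert len(scores) == 6
        assert by_name["mmd"] == pytest.approx(0.0, abs=1e-10)
        assert by_name["hellinger"] == pytest.approx(0.0, abs=1e-6)
        assert by_name["wasserstein"] == pytest.approx(0.0, abs=1e-10)
        assert by_name["cluster"] < 0.005
        assert by_name["propensity_mse"] < 0.01
        assert by_name["prediction_mse"] < 0.02

    def test_row_order_invariance_of_symmetric_metrics(self, sim_dataset):
        from synthutil import DEFAULT_METHODS, fit_and_sample

        syn = fit_and_sample(DEFAULT_METHODS[0], sim_dataset, replicate_seed=2)
        shuffled = syn.copy()
        shuffled.values = shuffled.values.sample(frac=1.0, random_state=1).reset_index(
            drop=True
        )
        a = {s.metric_name: s.value for s in compute_all_metrics(sim_dataset, syn)}
        b = {s.metric_name: s.value
             for s in compute_all_metrics(sim_dataset, shuffled)}
        for name in ("mmd", "hellinger", "wasserstein"):
            assert a[name] == pytest.approx(b[name], abs=1e-9)

    def test_negative_value_rejected_by_score_type(self):
        with pytest.raises(ValueError):
            UtilityScore(metric_name="mmd", value=-0.1)
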