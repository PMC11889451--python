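import numpy as np
import pytest

from miskit.exceptions import UnusableFeatureError, ValidationError
from miskit.imputation import (
    impute_iterative,
    impute_knn,
    impute_mice,
    impute_simple,
    pool_scalar,
    run_method,
)

from conftest import make_matrix


class TestSimple:
    def test_mean_fill(self):
        dm = make_matrix([[1.0, 0], [np.nan, 0], [3.0, 0]])
        res = impute_simple(dm, "mean")
        assert res.completed[1, 0] == pytest.approx(2.0)

    def test_most_frequent_tie_breaks_to_smallest(self):
        dm = make_matrix([[1.0, 0], [1.0, 0], [2.0, 0], [2.0, 0], [np.nan, 0]])
        res = impute_simple(dm, "most_frequent")
        assert res.completed[4, 0] == pytest.approx(1.0)

    def test_median_robust_to_outlier(self):
        dm = make_matrix([[1.0, 0], [2.0, 0], [np.nan, 0], [100.0, 0]])
        res = impute_simple(dm, "median")
        assert res.completed[2, 0] == pytest.approx(2.0)

    def test_all_missing_column_rejected(self):
        vals = np.ones((3, 2))
        vals[:, 1] = np.nan
        with pytest.raises(UnusableFeatureError):
            impute_simple(make_matrix(vals), "mean")


def _knn_oracle(values, k):
    """Brute-force nan-Euclidean KNN fill (uniform weights)."""
    n, p = values.shape
    out = values.copy()
    for i in range(n):
        for j in range(p):
            if not np.isnan(values[i, j]):
                continue
            dists = []
            for d in range(n):
                if d == i or np.isnan(values[d, j]):
                    continue
                shared = ~np.isnan(values[i]) & ~np.isnan(values[d])
                if not shared.any():
                    continue
                sq = np.mean((values[i, shared] - values[d, shared]) ** 2) * p
                dists.append((np.sqrt(sq), values[d, j]))
            dists.sort(key=lambda t: t[0])
            donors = [v for _, v in dists[:k]]
            out[i, j] = np.mean(donors) if donors else np.nanmean(values[:, j])
    return out


class TestKnn:
    def test_identical_row_donor_copies_value(self):
        vals = np.array(
            [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [50.0, 60.0, 70.0],
             [51.0, 61.0, 71.0]]
        )
        res = impute_knn(make_matrix(vals), k=1)
        assert res.completed[1, 2] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        vals = r.normal(size=(12, 3))
        # missing only in the target column keeps donor semantics unambiguous
        vals[r.choice(12, size=3, replace=False), 2] = np.nan
        res = impute_knn(make_matrix(vals), k=2, weighting="uniform")
        np.testing.assert_allclose(res.completed, _knn_oracle(vals, 2), atol=1e-10)

    def test_k_saturation_equals_plain_mean(self):
        vals = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 6.0], [1.0, np.nan]])
        res = impute_knn(make_matrix(vals), k=50)
        assert res.completed[3, 1] == pytest.approx(np.mean([1.0, 2.0, 6.0]))

    def test_invalid_k(self):
        with pytest.raises(ValidationError):
            impute_knn(make_matrix(np.ones((3, 2))), k=0)


class TestIterative:
    def test_recovers_exact_linear_relation(self, rng):
        x1 = rng.normal(size=30)
        vals = np.column_stack([x1, 2.0 * x1])
        vals[[3, 7, 11], 1] = np.nan
        res = impute_iterative(make_matrix(vals), learner="linear")
        np.testing.assert_allclose(
            res.completed[[3, 7, 11], 1], 2.0 * x1[[3, 7, 11]], atol=1e-6
        )

    def test_huge_tolerance_stops_after_one_round(self, correlated_gaussian):
        dm, _, _ = correlated_gaussian(n=80, seed=4)
        res = impute_iterative(dm, tol=1e9)
        assert res.n_iterations == 1 and res.converged

    def test_beats_mean_imputation_on_correlated_data(self, correlated_gaussian):
        dm, truth, mask = correlated_gaussian(n=200, rho=0.9, miss=0.2, seed=17)
        it = impute_iterative(dm, learner="linear")
        mean = impute_simple(dm, "mean")
        err_it = np.sqrt(np.mean((it.completed[mask] - truth[mask]) ** 2))
        err_mean = np.sqrt(np.mean((mean.completed[mask] - truth[mask]) ** 2))
        assert err_it < err_mean

    @pytest.mark.parametrize(
        "learner", ["linear", "lasso_cv", "random_forest", "gradient_boosting"]
    )
    def test_all_learners_complete_the_matrix(self, correlated_gaussian, learner):
        dm, _, _ = correlated_gaussian(n=60, seed=2)
        res = impute_iterative(dm, learner=learner, max_iter=2)
        assert not np.isnan(res.completed).any()


@pytest.mark.parametrize(
    "method",
    ["mean", "median", "most_frequent", "knn", "iterative", "lasso", "mice"],
)
class TestSuiteInvariants:
    def test_observed_cells_preserved_and_mask_reported(
        self, correlated_gaussian, method
    ):
        dm, _, mask = correlated_gaussian(n=60, seed=21)
        res = run_method(dm, method, seed=9)
        np.testing.assert_array_equal(res.imputed_mask, mask)
        np.testing.assert_array_equal(
            res.completed[~mask], dm.values[~mask]
        )
        assert not np.isnan(res.completed).any()

    def test_determinism_given_seed(self, correlated_gaussian, method):
        dm, _, _ = correlated_gaussian(n=50, seed=22)
        a = run_method(dm, method, seed=5)
        b = run_method(dm, method, seed=5)
        np.testing.assert_array_equal(a.completed, b.completed)


@pytest.mark.parametrize("method", ["mean", "median", "most_frequent", "knn"])
def test_fills_stay_inside_observed_range(correlated_gaussian, method):
    dm, _, mask = correlated_gaussian(n=70, seed=23)
    res = run_method(dm, method, seed=1)
    for j in range(dm.p):
        obs = dm.values[~mask[:, j], j]
        filled = res.completed[mask[:, j], j]
        assert np.all(filled >= obs.min() - 1e-12)
        assert np.all(filled <= obs.max() + 1e-12)


class TestMice:
    def test_complete_data_draws_identical(self, rng):
        dm = make_matrix(rng.normal(size=(40, 3)))
        mi = impute_mice(dm, m=3)
        for d in mi.draws:
            np.testing.assert_array_equal(d.completed, dm.values)
        assert np.all(mi.between_variance == 0)

    def test_total_variance_at_least_within(self, correlated_gaussian):
        dm, _, _ = correlated_gaussian(n=100, miss=0.25, seed=30)
        mi = impute_mice(dm, m=5)
        assert np.all(mi.total_variance >= mi.within_variance)
        assert np.all(mi.between_variance > 0)

    def test_pooled_means_recover_truth(self):
        r = np.random.default_rng(77)
        truth_mu = np.array([1.0, -2.0])
        X = r.multivariate_normal(truth_mu, [[1, 0.6], [0.6, 1]], size=800)
        vals = X.copy()
        vals[r.random(vals.shape) < 0.2] = np.nan
        mi = impute_mice(make_matrix(vals), m=5)
        se = np.sqrt(mi.total_variance)
        assert np.all(np.abs(mi.pooled_mean - truth_mu) < 3 * se + 0.1)

    def test_m_must_be_at_least_two(self, correlated_gaussian):
        dm, _, _ = correlated_gaussian(n=40, seed=1)
        with pytest.raises(ValidationError):
            impute_mice(dm, m=1)


def test_rubin_pooling_formula():
    est = np.array([[1.0], [2.0], [3.0]])
    var = np.array([[0.5], [0.5], [0.5]])
    pooled, within, between = pool_scalar(est, var)
    assert pooled[0] == pytest.approx(2.0)
    assert within[0] == pytest.approx(0.5)
    assert between[0] == pytest.approx(1.0)  # ddof=1 variance of {1,2,3}
    total = within + (1 + 1 / 3) * between
    assert total[0] == pytest.approx(0.5 + 4 / 3)
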