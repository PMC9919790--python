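import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from binimpute import (
    DayMatrix,
    GapSpec,
    ImputerConfig,
    apply_gap,
    impute,
    impute_em,
    impute_iterative,
    impute_knn,
    impute_rf,
    impute_simple,
)
from binimpute.exceptions import EmptyInputError, NumericalError

from .conftest import random_masked_matrix


def _matrix(values, offset=0):
    values = np.asarray(values, dtype=float)
    return DayMatrix([f"d{i}" for i in range(len(values))], values, offset)


class TestSimple:
    def test_column_mean_fill(self):
        m = _matrix([[60], [np.nan], [66], [72]])
        assert impute_simple(m).imputed.values[1, 0] == 66.0

    def test_fully_observed_is_identity(self, rng):
        m = random_masked_matrix(rng, missing=0.0)
        assert impute_simple(m).imputed.equals(m)

    def test_single_donor(self):
        m = _matrix([[np.nan], [50.0]])
        assert impute_simple(m).imputed.values[0, 0] == 50.0

    def test_all_missing_column_falls_back_to_grand_mean(self):
        m = _matrix([[np.nan, 10.0], [np.nan, 30.0]])
        assert impute_simple(m).imputed.values[0, 0] == 20.0

    def test_entirely_missing_matrix_rejected(self):
        m = _matrix([[np.nan], [np.nan]])
        with pytest.raises(EmptyInputError):
            impute_simple(m)

    def test_median_strategy(self):
        m = _matrix([[1.0], [2.0], [np.nan], [100.0]])
        res = impute_simple(m, ImputerConfig(method="SI", si_strategy="median"))
        assert res.imputed.values[2, 0] == 2.0


class TestEM:
    def test_fully_observed_identity_zero_iterations(self, rng):
        m = random_masked_matrix(rng, missing=0.0)
        res = impute_em(m)
        assert res.imputed.equals(m) and res.n_iterations == 0

    def test_bivariate_gaussian_conditional_mean(self):
        rng = np.random.default_rng(42)
        Z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=500)
        m = _matrix(np.vstack([Z, [np.nan, 1.0]]))
        res = impute_em(m)
        mu = Z.mean(axis=0)
        S = np.cov(Z.T, bias=True)
        oracle = mu[0] + S[0, 1] / S[1, 1] * (1.0 - mu[1])
        assert abs(res.imputed.values[-1, 0] - oracle) < 0.01
        # vs the true parameters the gap is dominated by the sampling noise
        # of the 500-row moments (sd ~ 1/sqrt(500)); allow a loose band
        assert abs(res.imputed.values[-1, 0] - 0.8) < 0.2

    def test_single_column_gap_gets_column_mean(self):
        m = _matrix([[10.0], [np.nan], [14.0]])
        assert impute_em(m).imputed.values[1, 0] == pytest.approx(12.0)

    def test_woodbury_path_matches_direct_covariance_solve(self, rng):
        # p_obs > n triggers the Gram-space solve; check it against the
        # textbook conditional mean computed from the full p x p covariance.
        n, p = 10, 40
        X = rng.normal(60, 5, size=(n, p))
        X[0, :5] = np.nan
        m = _matrix(X)
        cfg = ImputerConfig(method="EM", max_iter=1, ridge=1e-3)
        got = impute_em(m, cfg).imputed.values[0, :5]

        Xf = X.copy()
        col_mean = np.nanmean(Xf, axis=0)
        Xf[0, :5] = col_mean[:5]
        mu = Xf.mean(axis=0)
        Xc = Xf - mu
        lam = 1e-3 * np.var(Xf, axis=0).mean()
        Sigma = Xc.T @ Xc / n + lam * np.eye(p)
        obs, mis = np.arange(5, p), np.arange(5)
        w = np.linalg.solve(Sigma[np.ix_(obs, obs)], X[0, obs] - mu[obs])
        expected = mu[mis] + Sigma[np.ix_(mis, obs)] @ w
        np.testing.assert_allclose(got, expected, rtol=1e-8)

    def test_zero_ridge_on_degenerate_data_raises(self):
        vals = np.tile([50.0, 50.0, 50.0], (6, 1))  # zero variance everywhere
        vals[0, 0] = np.nan
        with pytest.raises(NumericalError, match="ridge"):
            impute_em(_matrix(vals), ImputerConfig(method="EM", ridge=0.0))

    def test_change_history_non_increasing_after_burn_in(self, rng):
        cov = 0.7 + 0.3 * np.eye(5)
        X = rng.multivariate_normal(np.full(5, 70.0), 9 * cov, size=40)
        mask = rng.random(X.shape) < 0.15
        mask[:, 0] &= ~mask[:, 1]  # keep rows partially observed
        X[mask] = np.nan
        res = impute_em(_matrix(X), ImputerConfig(method="EM", tol=1e-12, max_iter=60))
        h = res.history
        assert len(h) > 4
        assert all(h[i + 1] <= h[i] * (1 + 1e-9) for i in range(2, len(h) - 1))

    def test_em_beats_si_on_correlated_gaussian(self):
        """With inter-column correlation 0.75 and partially observed target
        rows, conditional-mean imputation should beat column means almost
        always."""
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            cov = 0.75 + 0.25 * np.eye(6)
            X = rng.multivariate_normal(np.full(6, 65.0), 16 * cov, size=40)
            truth = X.copy()
            hide = [(i, j) for i in range(10) for j in rng.choice(6, 2, replace=False)]
            for i, j in hide:
                X[i, j] = np.nan
            m = _matrix(X)
            em = impute_em(m).imputed.values
            si = impute_simple(m).imputed.values
            err = lambda Y: np.sqrt(np.mean([(Y[i, j] - truth[i, j]) ** 2 for i, j in hide]))
            wins += err(em) < err(si)
        assert wins >= 95, f"EM beat SI in only {wins}/100 replicates"


class TestKNN:
    def test_two_nearest_donor_mean(self):
        m = _matrix([[1, 1, 10], [1, 2, 20], [5, 5, 30], [1, 1, np.nan]])
        res = impute_knn(m, ImputerConfig(method="KNN", k=2))
        assert res.imputed.values[3, 2] == 15.0

    def test_fully_missing_row_with_large_k_equals_donor_column_means(self, rng):
        m = random_masked_matrix(rng, n=9, c=5, missing=0.0)
        m.values[4, :] = np.nan
        res = impute_knn(m, ImputerConfig(method="KNN", k=8))
        donors = np.delete(m.values, 4, axis=0)
        np.testing.assert_allclose(res.imputed.values[4], donors.mean(axis=0), rtol=1e-12)

    def test_fully_observed_identity(self, rng):
        m = random_masked_matrix(rng, missing=0.0)
        assert impute_knn(m).imputed.equals(m)

    def test_matches_sklearn_knnimputer(self, rng):
        sklearn = pytest.importorskip("sklearn.impute")
        m = random_masked_matrix(rng, n=12, c=6, missing=0.1)
        ours = impute_knn(m, ImputerConfig(method="KNN", k=3)).imputed.values
        theirs = sklearn.KNNImputer(n_neighbors=3).fit_transform(m.values)
        np.testing.assert_allclose(ours, theirs, rtol=1e-9)


class TestIterative:
    def test_recovers_exact_linear_relation(self):
        m = _matrix([[1, 2], [2, 4], [4, 8], [3, np.nan]])
        res = impute_iterative(m, ImputerConfig(method="II", ridge=1e-9))
        assert abs(res.imputed.values[3, 1] - 6.0) < 0.01

    def test_fully_observed_identity_zero_passes(self, rng):
        m = random_masked_matrix(rng, missing=0.0)
        res = impute_iterative(m)
        assert res.imputed.equals(m) and res.n_iterations == 0

    def test_independent_columns_regress_to_column_means(self, rng):
        X = rng.normal(70, 4, size=(60, 5))
        hidden = [(i, i % 5) for i in range(5)]
        col_means = X.mean(axis=0)
        for i, j in hidden:
            X[i, j] = np.nan
        res = impute_iterative(_matrix(X))
        for i, j in hidden:
            assert abs(res.imputed.values[i, j] - col_means[j]) < 3 * 4.0

    def test_single_column_falls_back_to_si(self):
        m = _matrix([[10.0], [np.nan], [14.0]])
        res = impute_iterative(m)
        assert res.imputed.values[1, 0] == 12.0
        assert res.config.method == "II"


class TestRF:
    def test_fully_observed_identity(self, rng):
        m = random_masked_matrix(rng, missing=0.0)
        assert impute_rf(m).imputed.equals(m)

    def test_constant_column_imputed_as_constant(self, rng):
        X = rng.normal(80, 6, size=(12, 4))
        X[:, 2] = 55.0
        X[3, 2] = np.nan
        res = impute_rf(_matrix(X), ImputerConfig(method="RF", n_trees=10))
        assert res.imputed.values[3, 2] == pytest.approx(55.0)

    def test_same_seed_bitwise_identical(self, rng):
        m = random_masked_matrix(rng, n=12, c=8, missing=0.15)
        cfg = ImputerConfig(method="RF", n_trees=15, seed=3)
        a = impute_rf(m, cfg).imputed
        b = impute_rf(m, cfg).imputed
        assert a.equals(b)

    def test_learns_strong_nonlinear_signal(self, rng):
        x = rng.uniform(-2, 2, size=80)
        X = np.column_stack([x, np.abs(x) * 10 + 60])  # nonlinear link
        X[5, 1] = np.nan
        res = impute_rf(_matrix(X), ImputerConfig(method="RF", n_trees=50))
        assert abs(res.imputed.values[5, 1] - (np.abs(x[5]) * 10 + 60)) < 6.0


class TestDispatcher:
    def test_si_route_matches_impute_simple(self, rng):
        m = random_masked_matrix(rng, missing=0.2)
        a = impute(m, ImputerConfig(method="SI")).imputed
        assert a.equals(impute_simple(m).imputed)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ImputerConfig(method="XYZ")

    @pytest.mark.parametrize("method", ["EM", "II", "KNN", "RF", "SI"])
    def test_observed_cells_preserved_and_no_missing_left(self, method):
        rng = np.random.default_rng(99)
        m = random_masked_matrix(rng, n=10, c=10, missing=0.2)
        cfg = ImputerConfig(method=method, n_trees=10)
        res = impute(m, cfg)
        obs = ~m.missing_mask
        assert np.array_equal(res.imputed.values[obs], m.values[obs])
        assert not np.isnan(res.imputed.values).any()

    @given(seed=st.integers(0, 500))
    def test_observed_preservation_property(self, seed):
        rng = np.random.default_rng(seed)
        m = random_masked_matrix(rng, n=7, c=5, missing=0.3)
        for method in ("SI", "KNN", "II", "EM"):
            res = impute(m, ImputerConfig(method=method))
            obs = ~m.missing_mask
            assert np.array_equal(res.imputed.values[obs], m.values[obs])
            assert np.isfinite(res.imputed.values).all()
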