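"""NIPALS PLS, component selection and the BCa bootstrap."""

import numpy as np
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from avidrivers.pls import (NipalsPLS, bootstrap_bca, nipals_pls,
                            pls_with_bootstrap, select_ncomp)


class TestNipalsPLS:
    def test_single_predictor_equals_standardized_simple_regression(self, rng):
        x = rng.normal(0, 2, 60)
        y = 1.5 - 0.8 * x + rng.normal(0, 0.5, 60)
        fit = nipals_pls(x[:, None], y, n_comp=1)
        r = stats.pearsonr(x, y).statistic   # standardized slope
        assert fit.coef[0] == pytest.approx(r, abs=1e-8)

    def test_orthogonal_response_gives_zero_coefficients(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        # orthogonalize y against centred X exactly
        Xc = X - X.mean(0)
        y = y - y.mean()
        y = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        fit = nipals_pls(X, y, n_comp=3)
        np.testing.assert_allclose(fit.coef, 0.0, atol=1e-8)

    def test_duplicated_column_shares_coefficient(self, rng):
        x = rng.normal(size=(40, 2))
        X = np.column_stack([x[:, 0], x[:, 0], x[:, 1]])
        y = x[:, 0] + rng.normal(0, 0.3, 40)
        fit = nipals_pls(X, y, n_comp=1)
        assert fit.coef[0] == pytest.approx(fit.coef[1], abs=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(80, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(size=80)
        est = NipalsPLS(n_components=5).fit(X, y)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        ols = np.linalg.lstsq(Z, yz, rcond=None)[0]
        np.testing.assert_allclose(est.coef_, ols, atol=1e-6)

    def test_matches_sklearn_on_complete_data(self, rng):
        """Independent-oracle check against sklearn's PLS (complete data)."""
        X = rng.normal(size=(60, 6))
        y = X[:, 0] - X[:, 3] + rng.normal(size=60)
        ours = NipalsPLS(n_components=3).fit(X, y)
        sk = PLSRegression(n_components=3, scale=True).fit(X, y)
        np.testing.assert_allclose(ours.predict(X), sk.predict(X).ravel(),
                                   atol=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        X = rng.normal(size=(50, 4))
        y = X[:, 1] + rng.normal(0, 0.5, 50)
        base = NipalsPLS(n_components=2).fit(X, y).coef_
        X2 = X.copy()
        X2[:, 1] = 100.0 * X2[:, 1] - 7.0
        again = NipalsPLS(n_components=2).fit(X2, y).coef_
        np.testing.assert_allclose(again, base, atol=1e-10)

    def test_constant_column_error_names_it(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 2] = 5.0
        with pytest.raises(ValueError, match="x2"):
            NipalsPLS(n_components=1).fit(X, rng.normal(size=30))

    def test_all_missing_column_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        X[:, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            NipalsPLS(n_components=1).fit(X, rng.normal(size=30))

    def test_missing_cells_tolerated(self, rng):
        X = rng.normal(size=(100, 4))
        y = -0.7 * X[:, 0] + rng.normal(0, 0.5, 100)
        X[rng.random((100, 4)) < 0.05] = np.nan
        fit = NipalsPLS(n_components=2).fit(X, y)
        assert np.isfinite(fit.coef_).all()
        assert fit.coef_[0] < -0.3    # dominant predictor survives missingness


class TestSelectNcomp:
    def test_one_latent_factor_selects_one(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            t = rng.normal(size=60)
            X = np.outer(t, rng.uniform(0.5, 1.5, 5)) + rng.normal(0, 0.1, (60, 5))
            y = t + rng.normal(0, 0.1, 60)
            hits += (select_ncomp(X, y, cv_repeats=3, seed=rep) == 1)
        assert hits >= 45

    def test_pure_noise_selects_minimum(self):
        picks = []
        for rep in range(20):
            rng = np.random.default_rng(2000 + rep)
            X = rng.normal(size=(50, 5))
            y = rng.normal(size=50)
            picks.append(select_ncomp(X, y, cv_repeats=3, seed=rep))
        assert np.mean(np.array(picks) == 1) >= 0.7

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 4))
        y = X[:, 0] + rng.normal(size=40)
        assert select_ncomp(X, y, seed=3) == select_ncomp(X, y, seed=3)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="cv_folds"):
            select_ncomp(rng.normal(size=(4, 2)), rng.normal(size=4),
                         cv_folds=5)


class TestBootstrapBca:
    def test_constant_data_zero_width(self):
        lo, hi, _ = bootstrap_bca(np.mean, np.full(20, 3.14), B=300, seed=0)
        assert lo[0] == hi[0] == pytest.approx(3.14)

    def test_symmetric_case_close_to_percentile(self, rng):
        """With z0 ~ 0 and a ~ 0 the BCa interval is the percentile one."""
        data = np.concatenate([-np.arange(1, 16), np.arange(1, 16)]) / 3.0
        lo, hi, info = bootstrap_bca(np.mean, data, B=4000, seed=1)
        rng2 = np.random.default_rng(1)
        boots = np.array([data[rng2.integers(0, len(data), len(data))].mean()
                          for _ in range(4000)])
        plo, phi = np.quantile(boots, [0.025, 0.975])
        assert info["acceleration"][0] == pytest.approx(0.0, abs=1e-12)
        assert lo[0] == pytest.approx(plo, abs=0.02)
        assert hi[0] == pytest.approx(phi, abs=0.02)

    def test_against_scipy_oracle(self, rng):
        data = rng.exponential(2.0, size=40)
        lo, hi, _ = bootstrap_bca(np.mean, data, B=4000, alpha=0.05, seed=2)
        res = stats.bootstrap((data,), np.mean, n_resamples=4000,
                              confidence_level=0.95, method="BCa",
                              random_state=2)
        assert lo[0] == pytest.approx(res.confidence_interval.low, abs=0.12)
        assert hi[0] == pytest.approx(res.confidence_interval.high, abs=0.12)

    def test_monotone_equivariance_on_exp(self, rng):
        data = rng.normal(0, 0.3, size=35)
        lo, hi, _ = bootstrap_bca(np.mean, data, B=3000, seed=4)
        lo_e, hi_e, _ = bootstrap_bca(lambda d: np.exp(np.mean(d)), data,
                                      B=3000, seed=4)
        assert lo_e[0] == pytest.approx(np.exp(lo[0]), rel=0.02)
        assert hi_e[0] == pytest.approx(np.exp(hi[0]), rel=0.02)

    def test_failing_statistic_raises(self, rng):
        def bad(d):
            raise RuntimeError("boom")
        data = rng.normal(size=20)
        with pytest.raises((RuntimeError, ValueError)):
            bootstrap_bca(bad, data, B=300, seed=0)

    def test_minimum_reps_enforced(self, rng):
        with pytest.raises(ValueError, match="B"):
            bootstrap_bca(np.mean, rng.normal(size=10), B=50, seed=0)


class TestPlsWithBootstrap:
    def test_trend_layout_shape_contract(self, rng):
        """Eight predictors (4 baselines + 4 trends), response per series."""
        X = rng.normal(size=(141, 8))
        y = -0.5 * X[:, 0] + rng.normal(size=141)
        fit = pls_with_bootstrap(X, y, n_boot=300, seed=0, cv_repeats=2)
        assert len(fit.coef) == 8 and len(fit.ci_lo) == 8
        assert fit.significant[0] and fit.coef[0] < 0

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(60, 4))
        y = X[:, 1] + rng.normal(size=60)
        a = pls_with_bootstrap(X, y, n_boot=300, seed=5, cv_repeats=2)
        b = pls_with_bootstrap(X, y, n_boot=300, seed=5, cv_repeats=2)
        np.testing.assert_array_equal(a.coef, b.coef)
        np.testing.assert_array_equal(a.ci_lo, b.ci_lo)
        assert a.n_comp == b.n_comp
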