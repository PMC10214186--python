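"""S-map local linear models, theta selection, block assembly, aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avidrivers.edm import CcmResult, standardize_segments
from avidrivers.simulate import CoupledLogisticSpec, gen_coupled_logistic
from avidrivers.smap import (SMapRegressor, aggregate_effects, build_block,
                             count_signed_effects, select_theta, smap_solve,
                             smap_weights)


def linear_system(n=120, noise=0.3, seed=0):
    A = np.array([[0.65, 0.25], [-0.25, 0.65]])
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 2))
    for t in range(n - 1):
        X[t + 1] = A @ X[t] + noise * rng.standard_normal(2)
    Z = (X - X.mean(0)) / X.std(0)
    return Z, A


class TestSmapSolve:
    def test_theta_zero_is_global_least_squares_everywhere(self):
        Z, _ = linear_system()
        X, y = Z[:-1], Z[1:, 0]
        fit = smap_solve(X, y, theta=0.0)
        Xa = np.hstack([np.ones((len(X), 1)), X])
        beta = np.linalg.lstsq(Xa, y, rcond=None)[0]
        assert np.abs(fit.coeffs_by_time - beta).max() < 1e-8

    def test_noise_free_linear_map_constant_coefficients_any_theta(self):
        # a noise-free autonomous spiral decays to zero variance, so use
        # random states with an exact linear response instead
        A = np.array([[0.65, 0.25], [-0.25, 0.65]])
        rng = np.random.default_rng(1)
        X0 = rng.standard_normal((80, 2))
        y = (X0 @ A.T)[:, 0]      # exact linear response, no dynamics noise
        for theta in (0.0, 1.0, 5.0):
            fit = smap_solve(X0, y, theta=theta)
            assert np.ptp(fit.coeffs_by_time, axis=0).max() < 1e-6
            np.testing.assert_allclose(fit.mean_coeffs, A[0], atol=1e-8)

    def test_constant_target_gives_zero_partials(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 2))
        fit = smap_solve(X, np.full(30, 2.5), theta=0.5)
        np.testing.assert_allclose(fit.mean_coeffs, 0.0, atol=1e-9)
        assert fit.intercept_mean == pytest.approx(2.5)

    def test_negative_theta_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="theta"):
            smap_solve(rng.standard_normal((20, 2)),
                       rng.standard_normal(20), theta=-1.0)

    def test_degenerate_states_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            smap_solve(np.ones((10, 2)), np.arange(10.0), theta=1.0)


class TestWeights:
    @given(st.floats(min_value=0.01, max_value=10.0))
    def test_self_weight_one_and_monotone_in_distance(self, theta):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((15, 3))
        w = smap_weights(X, 4, theta)
        d = np.linalg.norm(X - X[4], axis=1)
        assert w[4] == pytest.approx(1.0)
        assert ((w > 0) & (w <= 1)).all()
        order = np.argsort(d)
        assert (np.diff(w[order]) <= 1e-12).all()

    def test_doubling_theta_preserves_rank_order(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 2))
        w1 = smap_weights(X, 0, 1.0)
        w2 = smap_weights(X, 0, 2.0)
        np.testing.assert_array_equal(np.argsort(w1), np.argsort(w2))

    def test_theta_zero_all_weights_one(self):
        X = np.random.default_rng(9).standard_normal((12, 2))
        np.testing.assert_allclose(smap_weights(X, 3, 0.0), 1.0)


class TestSelectTheta:
    def test_linear_system_selects_zero_by_plateau_rule(self):
        Z, _ = linear_system(n=200, seed=3)
        theta = select_theta(Z[:-1], Z[1:, 0], seed=0)
        assert theta == 0.0

    def test_nonlinear_system_prefers_positive_theta(self):
        hits = 0
        for rep in range(10):
            df = gen_coupled_logistic(CoupledLogisticSpec(seed=300 + rep))
            ys = standardize_segments([g["y"].to_numpy()
                                       for _, g in df.groupby("segment")])
            xs = standardize_segments([g["x"].to_numpy()
                                       for _, g in df.groupby("segment")])
            X, y = [], []
            for a, b in zip(ys, xs):
                for t in range(len(a) - 1):
                    X.append([a[t], b[t]])
                    y.append(a[t + 1])
            hits += select_theta(np.array(X), np.array(y), seed=rep) > 0
        assert hits >= 8

    def test_deterministic_and_grid_validated(self):
        Z, _ = linear_system(seed=4)
        a = select_theta(Z[:-1], Z[1:, 0], seed=5)
        b = select_theta(Z[:-1], Z[1:, 0], seed=5)
        assert a == b
        with pytest.raises(ValueError, match="grid"):
            select_theta(Z[:-1], Z[1:, 0], grid=(0.0, 1.0), seed=0)


def fake_ccm(p, rho, convergent=True):
    return CcmResult(source="p", target="s", library_sizes=np.array([4, 16]),
                     rho_by_L=np.array([rho / 2, rho]),
                     sd_by_L=np.array([0.1, 0.05]), rho_full=rho,
                     p_value=p, convergent=convergent, E_used=2)


class TestBuildBlock:
    segs = [np.linspace(-1, 1, 10), np.linspace(1, -1, 10)]
    pressures = {k: [np.sin(np.arange(10) + i), np.cos(np.arange(10) + i)]
                 for i, k in enumerate(["a", "b", "c"])}

    def test_orders_by_p_value_and_truncates_to_e_minus_one(self):
        res = {"a": fake_ccm(0.02, 0.5), "b": fake_ccm(0.001, 0.6),
               "c": fake_ccm(0.04, 0.4)}
        block = build_block(self.segs, self.pressures, res, E=3)
        assert block.col_names == ["species", "b", "a"]

    def test_fills_with_lagged_species_columns(self):
        res = {"a": fake_ccm(0.01, 0.5), "b": fake_ccm(0.5, 0.1, False),
               "c": fake_ccm(0.9, 0.0, False)}
        block = build_block(self.segs, self.pressures, res, E=4)
        assert block.col_names == ["species", "a", "species_lag1",
                                   "species_lag2"]
        X, y = block.by_segment[0]
        assert X.shape == (7, 4)          # rows lost to 2 lags and 1 target
        np.testing.assert_allclose(X[:, 2], self.segs[0][1:8])

    def test_no_significant_pressure_sets_skip_flag(self):
        res = {"a": fake_ccm(0.5, 0.1, False)}
        block = build_block(self.segs, self.pressures, res, E=3)
        assert block.skipped and "no significant" in block.skip_reason

    def test_tie_breaks_by_descending_skill(self):
        res = {"a": fake_ccm(0.01, 0.3), "b": fake_ccm(0.01, 0.8)}
        block = build_block(self.segs, self.pressures, res, E=2)
        assert block.col_names == ["species", "b"]


class TestAggregation:
    @staticmethod
    def fit_with(coeffs, names):
        from avidrivers.smap import SmapFit
        return SmapFit(theta=0.0, col_names=names,
                       coeffs_by_time=np.zeros((5, len(names) + 1)),
                       mean_coeffs=np.asarray(coeffs, dtype=float),
                       intercept_mean=0.0, skill=0.9, n_obs=5)

    def test_single_country_passthrough(self):
        names = ["species", "farm_input"]
        fits = {"FR": self.fit_with([0.4, -0.3], names)}
        eff = aggregate_effects(fits, "sp1",
                                ccm_results={"farm_input": fake_ccm(0.01, 0.6)})
        assert len(eff) == 1
        assert eff[0].effect == pytest.approx(-0.3)
        assert eff[0].sign == "negative" and eff[0].significant

    def test_opposite_countries_cancel(self):
        names = ["species", "urban"]
        fits = {"FR": self.fit_with([0.1, 0.7], names),
                "DE": self.fit_with([0.1, -0.7], names)}
        eff = aggregate_effects(fits, "sp1", ccm_results={"urban": fake_ccm(0.5, 0.1, False)})
        assert eff[0].effect == pytest.approx(0.0)

    def test_bootstrap_significance_with_many_countries(self):
        names = ["species", "forest"]
        fits = {f"C{i}": self.fit_with([0.0, -0.5 - 0.01 * i], names)
                for i in range(10)}
        eff = aggregate_effects(fits, "sp1", seed=0)
        assert eff[0].significant and eff[0].n_countries == 10

    def test_lagged_columns_not_reported(self):
        names = ["species", "a", "species_lag1"]
        fits = {"FR": self.fit_with([0.1, -0.2, 0.05], names)}
        eff = aggregate_effects(fits, "sp1",
                                ccm_results={"a": fake_ccm(0.01, 0.5)})
        assert [e.pressure for e in eff] == ["a"]


class TestSignedCounts:
    def test_empty_is_all_zero(self):
        out = count_signed_effects([], pressures=["farm_input"])
        row = out.set_index("pressure").loc["farm_input"]
        assert (row == 0).all()

    def test_three_negative_two_positive(self):
        from avidrivers.smap import PressureEffect
        effs = [PressureEffect("s%d" % i, "urban", e, 3,
                               "negative" if e < 0 else "positive", True)
                for i, e in enumerate([-1, -2, -3, 1, 2])]
        row = count_signed_effects(effs).set_index("pressure").loc["urban"]
        assert (row["n_negative"], row["n_positive"], row["n_total"]) == (3, 2, 5)


class TestSMapRegressorEstimator:
    def test_fit_predict_and_params(self):
        Z, A = linear_system(seed=6)
        est = SMapRegressor(theta=0.0).fit(Z[:-1], Z[1:, 0])
        assert est.theta_ == 0.0
        pred = est.predict(Z[:-1][:5])
        assert pred.shape == (5,)
        assert est.get_params()["theta"] == 0.0
        est.set_params(theta=1.0)
        assert est.theta == 1.0

    def test_auto_theta_selection(self):
        Z, _ = linear_system(seed=7)
        est = SMapRegressor(theta=None, seed=0).fit(Z[:-1], Z[1:, 0])
        assert est.theta_ == 0.0   # linear system: plateau rule picks 0
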