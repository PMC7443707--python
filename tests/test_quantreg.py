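import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import check_loss_sum, lp_quantile_regression
from siqr.quantreg import (
    check_loss,
    default_h_grid,
    empirical_quantile,
    fit_quantile_lasso,
    post_l1_refit,
    predict_quantile,
    tune_h,
)


class TestCheckLoss:
    @pytest.mark.parametrize(
        "u,tau,expected",
        [(3.0, 0.5, 1.5), (-3.0, 0.5, 1.5), (1.0, 0.9, 0.9), (-1.0, 0.9, 0.1)],
    )
    def test_formula(self, u, tau, expected):
        assert check_loss(u, tau) == pytest.approx(expected)

    def test_invalid_tau(self):
        with pytest.raises(ValueError, match="tau"):
            check_loss(1.0, 1.0)

    @given(
        st.floats(-100, 100, allow_nan=False),
        st.floats(0.01, 0.99),
    )
    def test_nonnegative_and_zero_at_origin(self, u, tau):
        assert check_loss(u, tau) >= 0.0
        assert check_loss(0.0, tau) == 0.0

    @given(st.floats(0.05, 0.95), st.floats(0.1, 10))
    def test_positive_homogeneity(self, tau, scale):
        u = np.array([-2.0, -0.5, 1.0, 3.0])
        np.testing.assert_allclose(
            check_loss(scale * u, tau), scale * check_loss(u, tau), rtol=1e-12
        )

    def test_minimiser_is_empirical_quantile(self):
        """Grid search over candidate constants recovers the tau-quantile."""
        rng = np.random.default_rng(0)
        y = rng.standard_normal(37)
        for tau in (0.2, 0.5, 0.77):
            losses = [check_loss(y - q, tau) for q in y]
            best = y[int(np.argmin(losses))]
            assert best == pytest.approx(empirical_quantile(y, tau))


class TestFitQuantileLasso:
    def test_noiseless_exact_interpolation(self):
        rng = np.random.default_rng(1)
        nu = rng.standard_normal((50, 2))
        y = 2.0 + nu @ np.array([1.0, -3.0])
        m = fit_quantile_lasso(y, nu, tau=0.5, h_lasso=0.0)
        assert m.alpha_hat == pytest.approx(2.0, abs=1e-6)
        np.testing.assert_allclose(m.b_hat, [1.0, -3.0], atol=1e-6)

    def test_matches_independent_lp_formulation(self):
        """h=0 objective equals a free-variable LP oracle to 1e-8."""
        rng = np.random.default_rng(2)
        nu = rng.standard_normal((25, 2))
        y = 70 + nu @ np.array([2.0, -1.0]) + rng.standard_normal(25)
        for tau in (0.25, 0.75):
            m = fit_quantile_lasso(y, nu, tau=tau, h_lasso=0.0)
            obj = check_loss_sum(y - m.predict(nu), tau)
            _, _, obj_oracle = lp_quantile_regression(y, nu, tau)
            np.testing.assert_allclose(obj, obj_oracle, rtol=1e-8, atol=1e-8)

    def test_matches_statsmodels_quantreg(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        nu = rng.standard_normal((200, 3))
        y = 60 + nu @ np.array([1.5, 0.0, -2.0]) + rng.standard_normal(200)
        tau = 0.6
        m = fit_quantile_lasso(y, nu, tau=tau, h_lasso=0.0)
        sm_fit = sm.QuantReg(y, sm.add_constant(nu)).fit(q=tau)
        np.testing.assert_allclose(
            np.r_[m.alpha_hat, m.b_hat], sm_fit.params, atol=1e-4
        )

    def test_large_penalty_gives_null_model(self):
        rng = np.random.default_rng(4)
        nu = rng.standard_normal((23, 4))
        y = 70 + nu[:, 0] * 3 + rng.standard_normal(23)
        tau = 0.3  # 23 * 0.3 non-integer -> unique empirical quantile
        grid = default_h_grid(y, nu, tau)
        m = fit_quantile_lasso(y, nu, tau=tau, h_lasso=2.0 * grid[-1])
        np.testing.assert_array_equal(m.b_hat, 0.0)
        assert m.alpha_hat == pytest.approx(empirical_quantile(y, tau), abs=1e-9)
        assert m.support.size == 0

    def test_residual_sign_fraction_at_optimum(self):
        rng = np.random.default_rng(5)
        N, M = 120, 2
        nu = rng.standard_normal((N, M))
        y = 50 + nu @ np.array([1.0, 2.0]) + rng.standard_normal(N)
        for tau in (0.1, 0.5, 0.9):
            m = fit_quantile_lasso(y, nu, tau=tau, h_lasso=0.0)
            resid = y - m.predict(nu)
            frac_below = np.mean(resid < 0)
            assert abs(frac_below - tau) <= (M + 1) / N + 1e-12

    def test_objective_no_worse_than_null_model(self):
        rng = np.random.default_rng(6)
        nu = rng.standard_normal((60, 5))
        y = 70 + rng.standard_normal(60)
        tau, h = 0.5, 0.4
        m = fit_quantile_lasso(y, nu, tau=tau, h_lasso=h)
        scales = nu.std(axis=0, ddof=1)
        obj = check_loss_sum(y - m.predict(nu), tau) + h * np.abs(
            m.b_hat * scales
        ).sum()
        null_obj = check_loss_sum(y - empirical_quantile(y, tau), tau)
        assert obj <= null_obj + 1e-9

    def test_support_path_monotone_in_h(self):
        rng = np.random.default_rng(7)
        nu = rng.standard_normal((80, 6)) * np.array([3, 2, 1.5, 1, 1, 1])
        y = 70 + nu @ np.array([2.0, -1.2, 0.6, 0.0, 0.0, 0.0])
        y += 0.5 * rng.standard_normal(80)
        grid = default_h_grid(y, nu, 0.5, n_points=12)
        sizes = [
            fit_quantile_lasso(y, nu, 0.5, h_lasso=h).support.size for h in grid
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 0 or sizes[-1] < sizes[0]

    def test_slopes_constant_across_quantiles_under_linear_dgp(self):
        """With i.i.d. errors the slope does not depend on tau."""
        rng = np.random.default_rng(8)
        N = 2000
        nu = rng.standard_normal((N, 2)) * np.array([2.0, 1.0])
        y = 70 + nu @ np.array([1.0, -0.5]) + rng.standard_normal(N)
        slopes = [
            fit_quantile_lasso(y, nu, tau=t, h_lasso=0.0).b_hat
            for t in (0.25, 0.5, 0.75)
        ]
        for b in slopes[1:]:
            np.testing.assert_allclose(b, slopes[0], atol=0.12)

    def test_constant_response(self):
        nu = np.random.default_rng(9).standard_normal((20, 2))
        m = fit_quantile_lasso(np.full(20, 75.0), nu, tau=0.5, h_lasso=0.1)
        assert m.alpha_hat == pytest.approx(75.0, abs=1e-8)
        np.testing.assert_allclose(m.b_hat, 0.0, atol=1e-8)

    def test_scalar_covariates_unpenalised(self):
        rng = np.random.default_rng(10)
        nu = rng.standard_normal((100, 2))
        z = rng.standard_normal((100, 1))
        y = 70 + nu @ np.array([1.0, 0.5]) + z[:, 0] * 4.0
        m = fit_quantile_lasso(y, nu, tau=0.5, h_lasso=0.0, covariates=z)
        assert m.gamma_hat == pytest.approx(4.0, abs=1e-6)
        np.testing.assert_allclose(
            m.predict(nu, z), y, atol=1e-6
        )


class TestTuneH:
    def test_degenerate_grid(self):
        rng = np.random.default_rng(11)
        nu = rng.standard_normal((40, 2))
        y = 70 + nu[:, 0] + rng.standard_normal(40)
        res = tune_h(y, nu, 0.5, h_grid=[0.37], seed=0)
        assert res.chosen_h == 0.37

    def test_pure_noise_selects_sparse_model(self):
        """No signal: the tuned model keeps (almost) no covariates."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            nu = rng.standard_normal((100, 10))
            y = 70 + 2.0 * rng.standard_normal(100)
            res = tune_h(y, nu, 0.5, seed=rep)
            m = fit_quantile_lasso(y, nu, 0.5, h_lasso=res.chosen_h)
            hits += m.support.size <= 1
        assert hits >= 9

    def test_strong_signal_recovered(self):
        """Two informative scores among 20 noise ones are always kept."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            nu = rng.standard_normal((400, 22))
            y = 70 + nu[:, 0] * 3.0 - nu[:, 1] * 2.0 + rng.standard_normal(400)
            res = tune_h(y, nu, 0.5, h_grid=default_h_grid(y, nu, 0.5, 15),
                         seed=rep)
            m = fit_quantile_lasso(y, nu, 0.5, h_lasso=res.chosen_h)
            hits += {0, 1}.issubset(set(m.support))
        assert hits >= 9

    def test_fold_size_validation(self):
        with pytest.raises(ValueError, match="fold"):
            tune_h(np.arange(6.0), np.zeros((6, 1)), 0.5, n_folds=5)


class TestPostL1:
    def test_full_support_refit_equals_unpenalised_fit(self):
        rng = np.random.default_rng(12)
        nu = rng.standard_normal((50, 3))
        y = 70 + nu @ np.array([1.0, -1.0, 0.5]) + 0.3 * rng.standard_normal(50)
        m0 = fit_quantile_lasso(y, nu, 0.5, h_lasso=1e-8)
        assert m0.support.size == 3
        refit = post_l1_refit(m0, y, nu)
        exact = fit_quantile_lasso(y, nu, 0.5, h_lasso=0.0)
        np.testing.assert_allclose(refit.b_hat, exact.b_hat, atol=1e-6)
        assert refit.post_l1

    def test_empty_support_gives_empirical_quantile(self):
        rng = np.random.default_rng(13)
        nu = rng.standard_normal((31, 3))
        y = 70 + rng.standard_normal(31)
        grid = default_h_grid(y, nu, 0.7)
        m = fit_quantile_lasso(y, nu, 0.7, h_lasso=grid[-1] * 2)
        refit = post_l1_refit(m, y, nu)
        assert refit.alpha_hat == pytest.approx(
            empirical_quantile(y, 0.7), abs=1e-9
        )
        np.testing.assert_array_equal(refit.b_hat, 0.0)

    def test_refit_reduces_shrinkage_bias(self):
        """Over replicates the post-l1 slopes are closer to truth in MAD."""
        b_true = np.array([2.0, -1.5, 1.0, 0.0, 0.0])
        dev_lasso, dev_refit = [], []
        for rep in range(100):
            rng = np.random.default_rng(300 + rep)
            nu = rng.standard_normal((80, 5))
            y = 70 + nu @ b_true + rng.standard_normal(80)
            m = fit_quantile_lasso(y, nu, 0.5, h_lasso=8.0)
            r = post_l1_refit(m, y, nu)
            dev_lasso.append(np.abs(m.b_hat - b_true).mean())
            dev_refit.append(np.abs(r.b_hat - b_true).mean())
        assert np.mean(dev_refit) < np.mean(dev_lasso)


class TestPredict:
    def test_zero_scores_give_intercept(self):
        m = fit_quantile_lasso(
            70 + np.arange(20.0), np.random.default_rng(14).standard_normal((20, 2)),
            0.5, h_lasso=1e6,
        )
        np.testing.assert_allclose(
            predict_quantile(m, np.zeros((3, 2))), m.alpha_hat
        )

    def test_arithmetic(self):
        from siqr.quantreg import QuantileModel

        m = QuantileModel(
            tau=0.5, alpha_hat=70.0, b_hat=np.array([1.0, -2.0]),
            gamma_hat=None, h_lasso=0.0, support=np.array([0, 1]),
            standardization=np.ones(2),
        )
        assert predict_quantile(m, [[3.0, 1.0]])[0] == pytest.approx(71.0)

    def test_dimension_mismatch(self):
        m = fit_quantile_lasso(
            np.arange(10.0) + 60,
            np.random.default_rng(15).standard_normal((10, 2)), 0.5,
        )
        with pytest.raises(ValueError, match="columns"):
            predict_quantile(m, np.zeros((2, 3)))
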