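import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from caseonly.firth_logistic import FirthLogisticRegression, fit_logistic
from caseonly.riskset import build_case_only, caseonly_design
from caseonly.simdata import ScenarioConfig, generate_cohort


def _penalized_loglik_1d(x, y, offset, grid):
    """Independent evaluation of the Jeffreys-penalized likelihood for a
    single-column design, vectorized over a parameter grid."""
    eta = offset[None, :] + grid[:, None] * x[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = (y[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    info = (mu * (1 - mu) * x**2).sum(axis=1)
    return ll + 0.5 * np.log(info)


class TestPointEstimates:
    def test_firth_intercept_closed_form(self):
        """Intercept-only Jeffreys-penalized binomial: logit((y+1/2)/(n+1))."""
        m = FirthLogisticRegression(firth=True).fit(
            np.ones((10, 1)), np.r_[np.ones(3), np.zeros(7)]
        )
        assert m.coef_[0] == pytest.approx(math.log(3.5 / 7.5), abs=1e-7)
        assert m.converged_

    def test_ml_intercept_symmetry(self):
        m = FirthLogisticRegression(firth=False).fit(
            np.ones((10, 1)), np.r_[np.ones(5), np.zeros(5)]
        )
        assert m.coef_[0] == pytest.approx(0.0, abs=1e-9)

    def test_ml_matches_statsmodels_with_offset(self):
        rng = np.random.default_rng(0)
        n = 400
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.4, n)])
        offset = rng.normal(0, 0.5, n)
        eta = offset + 0.3 * X[:, 1] - 0.2
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        ours = FirthLogisticRegression(firth=False, tol=1e-10).fit(X, y, offset=offset)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset).fit()
        np.testing.assert_allclose(ours.coef_, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.se_, ref.bse, atol=1e-6)

    def test_firth_optimum_matches_grid_scan(self):
        """<=6-subject fixture: fine 1-D grid maximization is the oracle."""
        x = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        offset = np.array([0.1, -0.2, 0.0, 0.3, -0.1, 0.2])
        m = FirthLogisticRegression(firth=True, tol=1e-10).fit(
            x[:, None], y, offset=offset
        )
        grid = np.linspace(-6, 6, 1_200_001)
        vals = _penalized_loglik_1d(x, y, offset, grid)
        assert m.coef_[0] == pytest.approx(grid[vals.argmax()], abs=1e-4)
        assert m.loglik_ == pytest.approx(vals.max(), abs=1e-8)

    def test_separation_firth_finite_ml_diverges(self):
        X = np.column_stack([np.ones(8), np.r_[np.ones(4), np.zeros(4)]])
        y = np.r_[np.ones(4), np.zeros(4)]
        firth = FirthLogisticRegression(firth=True).fit(X, y)
        assert firth.converged_ and np.all(np.abs(firth.coef_) < 10)
        ml = FirthLogisticRegression(firth=False, max_iter=200).fit(X, y)
        assert (not ml.converged_) or np.max(np.abs(ml.coef_)) > 10

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError):
            FirthLogisticRegression().fit(X, np.r_[np.ones(3), np.zeros(3)])

    def test_offset_equivariance(self):
        """Adding c to all offsets shifts the intercept-like coefficient by
        -c and leaves the interaction coefficient unchanged."""
        rng = np.random.default_rng(3)
        n = 120
        M = rng.binomial(1, 0.3, n).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        offset = rng.normal(0, 0.3, n)
        X = np.column_stack([np.ones(n), M])
        c = 0.8
        a = FirthLogisticRegression(firth=True, tol=1e-10).fit(X, y, offset=offset)
        b = FirthLogisticRegression(firth=True, tol=1e-10).fit(X, y, offset=offset + c)
        assert b.coef_[0] == pytest.approx(a.coef_[0] - c, abs=1e-6)
        assert b.coef_[1] == pytest.approx(a.coef_[1], abs=1e-6)

    def test_score_zero_at_reported_optimum(self):
        rng = np.random.default_rng(5)
        n = 60
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.4, n)])
        y = rng.binomial(1, 0.3, n).astype(float)
        m = FirthLogisticRegression(firth=True, tol=1e-10).fit(X, y)
        eps = 1e-6
        for j in range(2):
            beta = m.coef_.copy()
            up, dn = beta.copy(), beta.copy()
            up[j] += eps
            dn[j] -= eps
            from caseonly.firth_logistic import _penalized_loglik

            llu = _penalized_loglik(X, y, np.zeros(n), up, True)[0]
            lld = _penalized_loglik(X, y, np.zeros(n), dn, True)[0]
            assert (llu - lld) / (2 * eps) == pytest.approx(0.0, abs=1e-4)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10**6))
def test_parametrization_consistency(seed):
    """gamma_I from the interaction design equals the subgroup contrast
    gamma_TM_high - gamma_TM_low: same penalized likelihood, linear
    reparametrization."""
    rng = np.random.default_rng(seed)
    n = rng.integers(10, 40)
    M = rng.binomial(1, 0.4, n).astype(float)
    if M.sum() in (0, n):
        M[0], M[-1] = 0.0, 1.0
    y = rng.binomial(1, 0.5, n).astype(float)
    offset = rng.normal(0, 0.5, n)
    Xi = np.column_stack([np.ones(n), M])
    Xs = np.column_stack([1 - M, M])
    fi = FirthLogisticRegression(firth=True, tol=1e-10).fit(Xi, y, offset=offset)
    fs = FirthLogisticRegression(firth=True, tol=1e-10).fit(Xs, y, offset=offset)
    assert fi.coef_[1] == pytest.approx(fs.coef_[1] - fs.coef_[0], abs=1e-6)
    assert fi.loglik_ == pytest.approx(fs.loglik_, abs=1e-8)


class TestProfileLikelihood:
    def test_bounds_match_grid_scan_intercept_only(self):
        m = FirthLogisticRegression(firth=True, tol=1e-12).fit(
            np.ones((10, 1)), np.r_[np.ones(3), np.zeros(7)]
        )
        (lo, hi), (ok_lo, ok_hi) = m.profile_ci(0)
        assert ok_lo and ok_hi
        grid = np.linspace(-6, 4, 2_000_001)
        vals = _penalized_loglik_1d(np.ones(10), np.r_[np.ones(3), np.zeros(7)],
                                    np.zeros(10), grid)
        thresh = vals.max() - 0.5 * 3.841458820694124
        inside = grid[vals >= thresh]
        assert lo == pytest.approx(inside[0], abs=1e-4)
        assert hi == pytest.approx(inside[-1], abs=1e-4)
        assert lo < m.coef_[0] < hi

    def test_profile_agrees_with_wald_large_sample(self):
        rng = np.random.default_rng(8)
        n = 100_000
        M = rng.binomial(1, 0.5, n).astype(float)
        eta = -0.4 + 0.5 * M
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(n), M])
        m = FirthLogisticRegression(firth=True).fit(X, y)
        (lo, hi), flags = m.profile_ci(1)
        assert all(flags)
        wald_lo, wald_hi = m.wald_ci()[1]
        assert (hi - lo) / (wald_hi - wald_lo) == pytest.approx(1.0, abs=0.02)

    def test_lr_test_dual_to_profile_ci(self):
        rng = np.random.default_rng(9)
        for seed in range(4):
            r = np.random.default_rng(seed)
            n = 40
            M = r.binomial(1, 0.4, n).astype(float)
            M[0], M[-1] = 0.0, 1.0
            y = r.binomial(1, 0.5, n).astype(float)
            X = np.column_stack([np.ones(n), M])
            m = FirthLogisticRegression(firth=True).fit(X, y)
            (lo, hi), flags = m.profile_ci(1)
            if not all(flags):
                continue
            p, ok = m.lr_test(1)
            assert ok
            excludes = lo > 0 or hi < 0
            assert excludes == (p < 0.05) or abs(p - 0.05) < 1e-3

    def test_symmetric_data_p_near_one(self):
        # M balanced, y independent of M and balanced within levels
        M = np.r_[np.zeros(8), np.ones(8)]
        y = np.r_[np.ones(4), np.zeros(4), np.ones(4), np.zeros(4)]
        X = np.column_stack([np.ones(16), M])
        m = FirthLogisticRegression(firth=True).fit(X, y)
        p, ok = m.lr_test(1)
        assert ok and p > 0.99
        assert m.coef_[1] == pytest.approx(0.0, abs=1e-8)


class TestFitLogisticWrapper:
    def test_result_contract(self, six_subject_cohort):
        co = build_case_only(six_subject_cohort)
        X, y, names = caseonly_design(co, "interaction")
        res = fit_logistic(X, y, offset=co["offset"].to_numpy(), firth=True,
                           names=names, profile=True)
        assert set(res.coefficients) == {"gamma_T", "gamma_I"}
        for nm in names:
            lo, hi = res.wald_ci[nm]
            est, se = res.coefficients[nm], res.model_se[nm]
            assert lo == pytest.approx(est - 1.959963984540054 * se)
            assert hi == pytest.approx(est + 1.959963984540054 * se)
            if all(res.pl_converged[nm]):
                plo, phi = res.pl_ci[nm]
                assert plo < est < phi
        assert res.converged and res.iterations < 1000

    def test_sklearn_param_interface(self):
        m = FirthLogisticRegression(firth=False, max_iter=77)
        params = m.get_params()
        assert params["max_iter"] == 77
        m.set_params(firth=True)
        assert m.firth
        with pytest.raises(ValueError):
            m.set_params(bogus=1)
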