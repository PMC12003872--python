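"""Cox proportional hazards with Firth-type penalized partial likelihood.

The penalized partial log-likelihood is ``pl*(b) = pl(b) + 0.5 log det I(b)``
with ``I`` the partial-likelihood information (Breslow ties), i.e. the
Heinze-Schemper construction of Firth's correction for Cox models.  The
modified score is

    U*_r(b) = U_r(b) + 0.5 * trace( I(b)^{-1} dI(b)/db_r ),

which requires third derivatives of the partial likelihood; these are
assembled from the weighted risk-set moments S0..S3.  Newton steps are
clipped element-wise to ``max_step``, mirroring the slow-but-safe solver
configuration typical for monotone-likelihood problems.

The designs arising in biomarker-treatment analyses take at most four
distinct covariate rows (functions of two binary factors), so risk-set
moments are accumulated over unique covariate patterns; fits cost
O(#event-times x #patterns) per iteration regardless of cohort size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .firth_logistic import FitResult, _chi2_quantile

__all__ = ["FirthCoxPH", "CoxFitResult", "fit_cox"]

CoxFitResult = FitResult


class _PartialLikelihood:
    """Breslow partial likelihood compressed over unique covariate patterns."""

    def __init__(self, X, time, event):
        X = np.asarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if event.sum() == 0:
            raise ValueError("no events: partial likelihood undefined")
        self.p = X.shape[1]
        Z, group = np.unique(X, axis=0, return_inverse=True)
        self.Z = Z  # (G, p)
        G = Z.shape[0]

        ev_times = np.unique(time[event == 1])  # ascending distinct event times
        K = ev_times.size
        # at-risk counts per (event time, pattern): #{time >= t_k, group == g}
        n_risk = np.zeros((K, G))
        d_x = np.zeros((K, self.p))  # sum of covariates over deaths at t_k
        d_k = np.zeros(K)
        for g in range(G):
            tg = np.sort(time[group == g])
            n_risk[:, g] = tg.size - np.searchsorted(tg, ev_times, side="left")
        death_t = time[event == 1]
        death_g = group[event == 1]
        k_idx = np.searchsorted(ev_times, death_t)
        np.add.at(d_k, k_idx, 1.0)
        np.add.at(d_x, k_idx, Z[death_g])
        self.n_risk, self.d_k, self.d_x = n_risk, d_k, d_x
        self.d_x_total = d_x.sum(axis=0)

    def moments(self, beta):
        Z = self.Z
        w = np.exp(Z @ beta)  # (G,)
        A = self.n_risk * w  # (K, G)
        S0 = A.sum(axis=1)  # (K,)
        S1 = A @ Z  # (K, p)
        S2 = np.einsum("kg,gr,gs->krs", A, Z, Z)
        S3 = np.einsum("kg,gr,gs,gt->krst", A, Z, Z, Z)
        return S0, S1, S2, S3

    def loglik(self, beta):
        S0 = (self.n_risk * np.exp(self.Z @ beta)).sum(axis=1)
        return float(self.d_x_total @ beta - np.sum(self.d_k * np.log(S0)))

    def derivatives(self, beta):
        """Score U, information I, and dI/db (p x p x p) at ``beta``."""
        S0, S1, S2, S3 = self.moments(beta)
        E = S1 / S0[:, None]  # (K, p)
        V = S2 / S0[:, None, None] - np.einsum("kr,ks->krs", E, E)
        U = self.d_x_total - self.d_k @ E
        info = np.einsum("k,krs->rs", self.d_k, V)
        S2n = S2 / S0[:, None, None]
        T3 = S3 / S0[:, None, None, None]
        dV = (
            T3
            - np.einsum("krs,kt->krst", S2n, E)
            - np.einsum("krt,ks->krst", S2n, E)
            - np.einsum("kst,kr->krst", S2n, E)
            + 2.0 * np.einsum("kr,ks,kt->krst", E, E, E)
        )
        dI = np.einsum("k,krst->rst", self.d_k, dV)
        ll = float(self.d_x_total @ beta - np.sum(self.d_k * np.log(S0)))
        return ll, U, info, dI


class FirthCoxPH:
    """Cox PH fitted by (optionally Firth-penalized) partial likelihood.

    Parameters
    ----------
    firth : bool, default True
        Use the Jeffreys-penalized partial likelihood; guarantees finite
        estimates under monotone likelihood (e.g. no events in a covariate
        pattern).
    max_iter : int, default 1000
    max_step : float, default 0.01
        Element-wise clip on each Newton step.
    tol : float, default 1e-6
        Max-norm tolerance on the (modified) score.
    step_tol : float, default 1e-7
        Alternative stopping rule on the Newton step max-norm; the score
        itself scales with the number of events, so on very large cohorts
        the parameter change is the sharper criterion.

    Attributes after ``fit``: ``coef_``, ``se_``, ``vcov_``, ``loglik_``
    (penalized when ``firth``), ``converged_`` (iterations strictly below
    ``max_iter``), ``n_iter_``.
    """

    def __init__(self, firth=True, max_iter=1000, max_step=0.01, tol=1e-6,
                 step_tol=1e-7):
        self.firth = firth
        self.max_iter = max_iter
        self.max_step = max_step
        self.tol = tol
        self.step_tol = step_tol

    def get_params(self, deep=True):
        return {
            "firth": self.firth,
            "max_iter": self.max_iter,
            "max_step": self.max_step,
            "tol": self.tol,
            "step_tol": self.step_tol,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, durations, event_observed):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient (collinear columns)")
        self._pl_ = _PartialLikelihood(X, durations, event_observed)
        beta, ll, info, converged, n_iter = self._solve(
            self._pl_, fixed=None, beta0=np.zeros(X.shape[1])
        )
        self.coef_ = beta
        self.loglik_ = ll
        self.vcov_ = np.linalg.inv(info)
        self.se_ = np.sqrt(np.diag(self.vcov_))
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def _penalized(self, pl, beta):
        ll, U, info, dI = pl.derivatives(beta)
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf, U, info, dI
        if self.firth:
            ll += 0.5 * logdet
        return ll, U, info, dI

    def _solve(self, pl, fixed, beta0):
        p = pl.p
        beta = beta0.astype(float).copy()
        free = np.arange(p)
        if fixed is not None:
            k, val = fixed
            beta[k] = val
            free = np.array([j for j in range(p) if j != k])
        if free.size == 0:
            ll, *_ = self._penalized(pl, beta)
            return beta, ll, pl.derivatives(beta)[2], True, 0
        ll, U, info, dI = self._penalized(pl, beta)
        converged = False
        it = 0
        cap = self.max_step  # adaptive trust-region cap, never above max_step
        stall = 0
        for it in range(1, self.max_iter + 1):
            score = U.copy()
            if self.firth:
                try:
                    info_inv = np.linalg.inv(info)
                except np.linalg.LinAlgError:
                    break
                score = score + 0.5 * np.einsum("rs,rst->t", info_inv, dI)
            score_free = score[free]
            if np.max(np.abs(score_free)) < self.tol:
                converged = True
                it -= 1
                break
            info_ff = info[np.ix_(free, free)]
            try:
                step = np.linalg.solve(info_ff, score_free)
            except np.linalg.LinAlgError:
                break
            if np.max(np.abs(step)) < self.step_tol:
                converged = True
                it -= 1
                break
            clipped = np.clip(step, -cap, cap)
            if clipped @ score_free <= 0.0:
                # element-wise clipping flipped the ascent direction;
                # shrink the whole Newton vector instead
                clipped = step * (cap / np.max(np.abs(step)))
            step = clipped
            new_ll = -np.inf
            n_halved = 0
            for n_halved in range(25):
                cand = beta.copy()
                cand[free] += step
                new_ll, nU, ninfo, ndI = self._penalized(pl, cand)
                if new_ll >= ll - 1e-12 * max(1.0, abs(ll)):
                    break
                step *= 0.5
            if not np.isfinite(new_ll):
                break
            cap = max(cap * 0.5**n_halved, 1e-8) if n_halved else min(
                cap * 2.0, self.max_step)
            stall = stall + 1 if abs(new_ll - ll) < 4e-15 * max(1.0, abs(ll)) else 0
            beta, ll, U, info, dI = cand, new_ll, nU, ninfo, ndI
            if stall >= 3:
                converged = True
                break
        return beta, ll, info, converged, it

    # -- inference ---------------------------------------------------------
    def wald_ci(self, level=0.95):
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.coef_ - z * self.se_, self.coef_ + z * self.se_])

    def wald_p_values(self):
        z = self.coef_ / self.se_
        return 2.0 * stats.norm.sf(np.abs(z))

    def _profile_loglik(self, k, value, beta_start):
        beta, ll, _, conv, _ = self._solve(self._pl_, fixed=(k, value),
                                           beta0=beta_start.copy())
        return ll, conv, beta

    def profile_ci(self, k, level=0.95, max_evals=200):
        """Profile penalized-partial-likelihood CI; same contract as the
        logistic version (per-bound convergence flags)."""
        if not self.converged_:
            raise ValueError("profile CI requires a converged fit")
        target = 0.5 * _chi2_quantile(level)
        out, flags = [], []
        for direction in (-1.0, 1.0):
            b, ok = self._profile_bound(k, direction, target, max_evals)
            out.append(b)
            flags.append(ok)
        return (out[0], out[1]), (flags[0], flags[1])

    def _profile_bound(self, k, direction, target, max_evals):
        from scipy import optimize

        center = self.coef_[k]
        ll_hat = self.loglik_
        n_eval = 0
        warm = self.coef_.copy()

        def g(b):
            nonlocal n_eval, warm
            n_eval += 1
            ll, conv, beta = self._profile_loglik(k, b, warm)
            if conv:
                warm = beta
            return (ll_hat - ll) - target

        step = max(self.se_[k], 1e-2)
        lo_b, hi_b = center, None
        for _ in range(60):
            if n_eval > max_evals:
                return np.nan, False
            cand = center + direction * step
            val = g(cand)
            if np.isnan(val):
                return np.nan, False
            if val > 0:
                hi_b = cand
                break
            lo_b = cand
            step *= 1.6
        if hi_b is None:
            return np.nan, False
        try:
            root = optimize.brentq(g, min(lo_b, hi_b), max(lo_b, hi_b),
                                   xtol=1e-6, maxiter=max(10, max_evals - n_eval))
        except (ValueError, RuntimeError):
            return np.nan, False
        if n_eval > max_evals:
            return np.nan, False
        return float(root), True

    def lr_test(self, k):
        ll0, conv, _ = self._profile_loglik(k, 0.0, np.zeros_like(self.coef_))
        if not conv:
            return np.nan, False
        dev = max(0.0, 2.0 * (self.loglik_ - ll0))
        return float(stats.chi2.sf(dev, df=1)), True


_PARAMETRIZATIONS = {
    "interaction": (("M", "T", "MT"), ("beta_M", "beta_T", "beta_I")),
    "subgroup": (("M", "TM_low", "TM_high"), ("beta_M", "beta_TM_low", "beta_TM_high")),
}


def cox_design(cohort: pd.DataFrame, parametrization: str) -> np.ndarray:
    """Design matrix for the full-cohort model.

    ``interaction``: columns (M, T, M*T).  ``subgroup``: columns
    (M, TM_low, TM_high) with TM_low = T*(1-M) and TM_high = T*M, so the
    treatment effect is estimated separately within each marker level.
    """
    if parametrization not in _PARAMETRIZATIONS:
        raise ValueError(f"unknown parametrization {parametrization!r}")
    M = cohort["M"].to_numpy(float)
    T = cohort["T"].to_numpy(float)
    if parametrization == "interaction":
        return np.column_stack([M, T, M * T])
    return np.column_stack([M, T * (1 - M), T * M])


def fit_cox(cohort, parametrization="interaction", firth=True, max_iter=1000,
            max_step=0.01, level=0.95, profile=False) -> CoxFitResult:
    """Fit the full-cohort Cox comparator; returns the FitResult contract.

    Non-convergence is reported through ``converged``; zero events raise.
    """
    X = cox_design(cohort, parametrization)
    names = _PARAMETRIZATIONS[parametrization][1]
    model = FirthCoxPH(firth=firth, max_iter=max_iter, max_step=max_step)
    model.fit(X, cohort["time"].to_numpy(), cohort["event"].to_numpy())
    wald = model.wald_ci(level)
    wald_p = model.wald_p_values()
    res = CoxFitResult(
        coefficients={nm: float(model.coef_[j]) for j, nm in enumerate(names)},
        model_se={nm: float(model.se_[j]) for j, nm in enumerate(names)},
        vcov=model.vcov_,
        loglik=model.loglik_,
        converged=bool(model.converged_),
        iterations=int(model.n_iter_),
        wald_ci={nm: (float(wald[j, 0]), float(wald[j, 1])) for j, nm in enumerate(names)},
        p_value={nm: float(wald_p[j]) for j, nm in enumerate(names)},
        names=tuple(names),
    )
    if profile and model.converged_:
        for j, nm in enumerate(names):
            (lo, hi), (ok_lo, ok_hi) = model.profile_ci(j, level)
            res.pl_ci[nm] = (lo, hi)
            res.pl_converged[nm] = (ok_lo, ok_hi)
            pval, ok = model.lr_test(j)
            res.pl_p_value[nm] = pval if ok else np.nan
    res.model = model
    return res
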