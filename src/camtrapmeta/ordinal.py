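"""Proportional-odds (cumulative logit) regression by direct maximum
likelihood.

The model for an ordinal response with J ordered categories is

    P(Y <= j | x) = logistic(theta_j - x beta),    j = 1..J-1,

with strictly ascending thresholds theta and a common slope vector beta.
Under this link convention a positive beta means larger covariate values
push probability mass towards the higher (more camera-favourable)
categories; with film coded 1 and digital as the reference, a
camera-favourable disadvantage of film shows up as a negative film
coefficient.

Fitting maximizes the multinomial log-likelihood by gradient-based
optimization from a deterministic start (thresholds at the empirical
cumulative logits, slopes at zero), so fits are reproducible without
seeds.  Standard errors come from the observed information (numerically
differentiated analytic gradient).  Complete separation shows up as
non-convergence and is flagged rather than raised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .modsel import AveragedEstimate


def _nat_loglik_grad(theta: np.ndarray, beta: np.ndarray,
                     X: np.ndarray, y: np.ndarray, J: int):
    """Log-likelihood and gradient in the natural (theta, beta) space."""
    eta = X @ beta if X.size else np.zeros(len(y))
    # cumulative probabilities gamma_j = sigma(theta_j - eta), j=1..J-1
    z = theta[None, :] - eta[:, None]               # (n, J-1)
    gamma = expit(z)
    dgamma = gamma * (1.0 - gamma)                  # sigma'
    gfull = np.concatenate(
        [np.zeros((len(y), 1)), gamma, np.ones((len(y), 1))], axis=1)
    dfull = np.concatenate(
        [np.zeros((len(y), 1)), dgamma, np.zeros((len(y), 1))], axis=1)
    probs = gfull[np.arange(len(y)), y + 1] - gfull[np.arange(len(y)), y]
    probs = np.clip(probs, 1e-300, None)
    ll = float(np.log(probs).sum())

    d_upper = dfull[np.arange(len(y)), y + 1]       # sigma' at theta_{y+1}
    d_lower = dfull[np.arange(len(y)), y]           # sigma' at theta_y
    inv_p = 1.0 / probs
    # d ll / d theta_j: +sigma'_j/p for y == j-1 (upper cut), -sigma'_j/p for y == j
    g_theta = np.zeros(J - 1)
    for j in range(1, J):
        upper_mask = y == j - 1
        lower_mask = y == j
        g_theta[j - 1] = (dfull[upper_mask, j] * inv_p[upper_mask]).sum() \
            - (dfull[lower_mask, j] * inv_p[lower_mask]).sum()
    # d ll / d beta = sum_i x_i * (d_lower - d_upper)/p
    g_beta = X.T @ ((d_lower - d_upper) * inv_p) if X.size else np.zeros(0)
    return ll, g_theta, g_beta


class ProportionalOddsModel(BaseEstimator):
    """Cumulative-logit regression fitted by direct ML.

    Parameters
    ----------
    n_categories : int or None
        Number of ordered response categories J; inferred from the data
        when None.  The response ``y`` holds integer codes 0..J-1.
    tol : float, default 1e-6
        Infinity-norm gradient tolerance for the ``converged_`` flag.

    Attributes (after fit)
    ----------------------
    thresholds_ : ndarray (J-1,), strictly ascending cutpoints.
    coef_, bse_ : ndarray (p,), slopes and their SEs.
    coef_named_, bse_named_ : dict column name -> value.
    loglik_, nobs_, n_params_ : fit summaries; k = p + (J-1).
    converged_ : bool.
    """

    def __init__(self, n_categories: int | None = None, tol: float = 1e-6,
                 max_iter: int = 500):
        self.n_categories = n_categories
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_ = list(X.columns)
        Xa = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=int)
        J = self.n_categories or int(y.max()) + 1
        if np.unique(y).size < 2:
            raise ValueError("response must have observations in >= 2 categories")
        n, p = len(y), Xa.shape[1]
        self.n_categories_ = J

        # deterministic start: empirical cumulative logits, slopes 0
        counts = np.bincount(y, minlength=J).astype(float)
        cum = np.clip(np.cumsum(counts)[:-1] / n, 1.0 / (n + 1), n / (n + 1))
        theta0 = np.log(cum / (1.0 - cum))
        theta0 = np.maximum.accumulate(theta0 + 1e-8 * np.arange(J - 1))

        # unconstrained parameterization: (t1, log gaps, beta)
        def unpack(z):
            t1 = z[0]
            gaps = np.exp(z[1:J - 1])
            theta = np.concatenate([[t1], t1 + np.cumsum(gaps)])
            return theta, z[J - 1:]

        def negloglik(z):
            theta, beta = unpack(z)
            ll, g_t, g_b = _nat_loglik_grad(theta, beta, Xa, y, J)
            # chain rule: d theta_m / d t1 = 1; d theta_m / d z_g = gap_g for m > g
            g_z = np.empty_like(z)
            g_z[0] = g_t.sum()
            gaps = np.exp(z[1:J - 1])
            for g in range(J - 2):
                g_z[1 + g] = g_t[g + 1:].sum() * gaps[g]
            g_z[J - 1:] = g_b
            return -ll, -g_z

        z0 = np.concatenate([
            [theta0[0]],
            np.log(np.maximum(np.diff(theta0), 1e-6)),
            np.zeros(p),
        ])
        res = minimize(negloglik, z0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter, "ftol": 1e-14,
                                "gtol": 1e-10})
        theta, beta = unpack(res.x)
        theta, beta, ll, gradnorm = self._newton_polish(theta, beta, Xa, y, J)
        # a vanishing gradient at huge parameter values means the likelihood
        # is maximized at infinity (complete separation), not convergence
        diverged = bool(
            (np.abs(beta).max(initial=0.0) > 30.0)
            or (np.abs(theta).max() > 100.0))
        self.converged_ = bool(gradnorm < self.tol) and not diverged
        self.thresholds_ = theta
        self.coef_ = beta
        self.loglik_ = ll
        self.nobs_ = n
        self.n_params_ = p + (J - 1)

        cov = self._observed_cov(theta, beta, Xa, y, J)
        self.thresholds_bse_ = np.sqrt(np.maximum(np.diag(cov)[:J - 1], 0.0))
        self.bse_ = np.sqrt(np.maximum(np.diag(cov)[J - 1:], 0.0))
        self.coef_named_ = dict(zip(self.feature_names_, self.coef_))
        self.bse_named_ = dict(zip(self.feature_names_, self.bse_))
        return self

    @staticmethod
    def _newton_polish(theta, beta, X, y, J, max_steps: int = 25):
        """Newton refinement in the natural (theta, beta) space, with step
        halving and a threshold-ordering guard.  Quasi-Newton optimization
        can stop on a flat likelihood a hair short of the gradient
        tolerance; a few Newton steps close the gap."""
        def eval_at(v):
            th, be = v[:J - 1], v[J - 1:]
            ll, g_t, g_b = _nat_loglik_grad(th, be, X, y, J)
            return ll, np.concatenate([g_t, g_b])

        v = np.concatenate([theta, beta])
        ll, g = eval_at(v)
        for _ in range(max_steps):
            if np.abs(g).max() < 1e-10:
                break
            H = ProportionalOddsModel._fd_hessian(v, X, y, J)
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            improved = False
            for _ in range(30):
                cand = v + scale * step
                if np.all(np.diff(cand[:J - 1]) > 0):
                    ll_c, g_c = eval_at(cand)
                    if ll_c >= ll - 1e-12:
                        v, ll, g = cand, ll_c, g_c
                        improved = True
                        break
                scale *= 0.5
            if not improved:
                break
        return v[:J - 1], v[J - 1:], ll, float(np.abs(g).max())

    @staticmethod
    def _fd_hessian(params, X, y, J):
        m = len(params)

        def grad(v):
            th, be = v[:J - 1], v[J - 1:]
            _, g_t, g_b = _nat_loglik_grad(th, be, X, y, J)
            return np.concatenate([g_t, g_b])

        H = np.zeros((m, m))
        for i in range(m):
            h = 1e-5 * (1.0 + abs(params[i]))
            vp, vm = params.copy(), params.copy()
            vp[i] += h
            vm[i] -= h
            H[:, i] = (grad(vp) - grad(vm)) / (2.0 * h)
        return 0.5 * (H + H.T)

    @staticmethod
    def _observed_cov(theta, beta, X, y, J):
        """Covariance from the observed information, via central finite
        differences of the analytic gradient."""
        params = np.concatenate([theta, beta])
        H = ProportionalOddsModel._fd_hessian(params, X, y, J)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.full((len(params), len(params)), np.nan)
        return cov

    def predict_proba(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        Xa = X.to_numpy(dtype=float)
        eta = Xa @ self.coef_ if Xa.size else np.zeros(len(X))
        gamma = expit(self.thresholds_[None, :] - eta[:, None])
        gfull = np.concatenate(
            [np.zeros((len(X), 1)), gamma, np.ones((len(X), 1))], axis=1)
        return np.diff(gfull, axis=1)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def fit_proportional_odds(design, terms=None) -> ProportionalOddsModel:
    """Fit the cumulative-logit model on a :class:`StandardizedDesign`,
    restricted to the given design columns (all columns when None)."""
    frame = design.frame if terms is None else design.frame.loc[:, list(terms)]
    return ProportionalOddsModel().fit(frame, design.response)


def odds_ratio(estimate: float | AveragedEstimate) -> float:
    """Odds-ratio interpretation of a slope for a non-reference factor
    level: exp(-estimate) is the factor by which the reference level raises
    the odds of a more camera-favourable recommendation (e.g. a film
    coefficient of -1.42 means digital cameras raise those odds 4.1-fold)."""
    if isinstance(estimate, AveragedEstimate):
        estimate = estimate.estimate
    return float(np.exp(-estimate))


__all__ = ["ProportionalOddsModel", "fit_proportional_odds", "odds_ratio"]
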