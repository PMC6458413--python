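"""Random-intercept linear mixed models by profiled maximum likelihood,
and the variance-inflation-factor collinearity screen.

The model for effect size y_ij (comparison j of study i) is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_study),
                                      e_ij ~ N(0, s2_resid),

so two rows from the same study share covariance s2_study.  Writing
lambda = s2_study / s2_resid, the marginal covariance is
s2_resid * V(lambda) with V block-diagonal, V_i = I + lambda * J.  For
fixed lambda the GLS fixed effects and the ML residual variance are closed
form, using the Woodbury identity per study block:

    V_i^{-1} = I - (lambda / (1 + lambda n_i)) J,
    log|V_i| = log(1 + lambda n_i),

so profiling reduces the fit to a one-dimensional bounded search over
lambda.  ML (not REML) is used throughout because candidate models differ
in their fixed effects and are compared by AICc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin


class RankDeficientDesign(ValueError):
    """The fixed-effects design has aliased (linearly dependent) columns."""


@dataclass
class VifReport:
    vif: dict[str, float]          # per design column
    max_vif: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"column": k, "vif": v} for k, v in self.vif.items()])


class RandomInterceptLMM(BaseEstimator, RegressorMixin):
    """Linear mixed model with a single random intercept, fitted by ML.

    Parameters
    ----------
    add_intercept : bool, default True
        Prepend an intercept column to the fixed-effects design.
    lambda_max : float, default 1e6
        Upper bound of the variance-ratio search interval [0, lambda_max].
    tol : float, default 1e-8
        Absolute tolerance of the one-dimensional lambda optimization.
    lambda_fixed : float or None, default None
        Fix the variance ratio instead of profiling it (lambda_fixed=0
        collapses the model to ordinary Gaussian least squares).

    Attributes (after fit)
    ----------------------
    coef_, bse_ : fixed-effect estimates and GLS standard errors
        (intercept first when ``add_intercept``).
    coef_named_, bse_named_ : dict design column -> value (no intercept key
        unless the design contains one).
    sigma2_study_, sigma2_resid_, lambda_ : variance components.
    loglik_ : full ML log-likelihood.
    n_params_ : fixed-effect columns + 2 variance components.
    boundary_ : True when lambda sits on the search boundary (e.g. a
        one-comparison-per-study design, where the ratio is unidentifiable).
    """

    def __init__(self, add_intercept: bool = True, lambda_max: float = 1e6,
                 tol: float = 1e-8, lambda_fixed: float | None = None):
        self.add_intercept = add_intercept
        self.lambda_max = lambda_max
        self.tol = tol
        self.lambda_fixed = lambda_fixed

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("RandomInterceptLMM.fit requires groups=")
        X = pd.DataFrame(X)
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if self.add_intercept:
            Xa = np.column_stack([np.ones(n), Xa])
            names = ["(intercept)"] + names
        p = Xa.shape[1]

        # rank screen, naming aliased columns via QR pivoting
        _, R, piv = qr(Xa, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol_rank = diag.max() * max(Xa.shape) * np.finfo(float).eps if diag.size else 0
        rank = int((diag > tol_rank).sum())
        if rank < p:
            aliased = [names[j] for j in piv[rank:]]
            raise RankDeficientDesign(
                f"fixed-effects design is rank deficient; aliased column(s): "
                f"{aliased}")

        codes, _ = pd.factorize(np.asarray(groups), sort=True)
        n_groups = codes.max() + 1
        if n_groups < 2:
            raise ValueError("need >= 2 studies to fit a study random intercept")
        counts = np.bincount(codes).astype(float)

        # per-group sums, precomputed once: profile evaluations are O(S p^2)
        S_x = np.zeros((n_groups, p))
        np.add.at(S_x, codes, Xa)
        S_y = np.bincount(codes, weights=y)
        XtX = Xa.T @ Xa
        Xty = Xa.T @ y
        yty = float(y @ y)

        def profile(lam):
            """Profile negative log-likelihood at variance ratio lam;
            returns (nll, beta, sigma2, XtVinvX)."""
            w = lam / (1.0 + lam * counts)                       # per group
            XtVX = XtX - (S_x * w[:, None]).T @ S_x
            XtVy = Xty - S_x.T @ (w * S_y)
            yVy = yty - float(w @ S_y**2)
            beta = np.linalg.solve(XtVX, XtVy)
            rss = yVy - float(beta @ XtVy)
            sigma2 = max(rss / n, 1e-300)
            logdet = float(np.log1p(lam * counts).sum())
            ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
            return -ll, beta, sigma2, XtVX

        if self.lambda_fixed is not None:
            lam = float(self.lambda_fixed)
            nll, beta, sigma2, XtVX = profile(lam)
            return self._finalize(lam, nll, beta, sigma2, XtVX, names, n, p,
                                  counts)

        # coarse log-spaced scan, then bounded refinement around the best
        grid = np.concatenate([[0.0], np.logspace(-8, np.log10(self.lambda_max), 61)])
        nlls = np.array([profile(l)[0] for l in grid])
        i = int(nlls.argmin())
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda l: profile(l)[0], bounds=(lo, hi), method="bounded",
                options={"xatol": self.tol, "maxiter": 500})
            lam = float(res.x) if res.fun <= nlls[i] else float(grid[i])
        else:
            lam = float(grid[i])

        nll, beta, sigma2, XtVX = profile(lam)
        return self._finalize(lam, nll, beta, sigma2, XtVX, names, n, p, counts)

    def _finalize(self, lam, nll, beta, sigma2, XtVX, names, n, p, counts):
        self.lambda_ = lam
        self.sigma2_resid_ = float(sigma2)
        self.sigma2_study_ = float(lam * sigma2)
        self.loglik_ = -float(nll)
        self.coef_ = beta
        cov = np.linalg.inv(XtVX) * sigma2
        self.bse_ = np.sqrt(np.diag(cov))
        self.feature_names_ = names
        self.coef_named_ = {nm: b for nm, b in zip(names, beta)
                            if nm != "(intercept)"}
        self.bse_named_ = {nm: s for nm, s in zip(names, self.bse_)
                           if nm != "(intercept)"}
        self.nobs_ = n
        self.n_params_ = p + 2
        self.converged_ = True
        self.boundary_ = bool(lam <= 1e-10 or lam >= self.lambda_max * (1 - 1e-9))
        if np.all(counts == 1):
            self.boundary_ = True
            warnings.warn(
                "one comparison per study: the variance ratio is "
                "unidentifiable and sits on a likelihood plateau",
                stacklevel=2)
        return self

    def predict(self, X) -> np.ndarray:
        """Population-level (fixed-effects only) prediction."""
        Xa = pd.DataFrame(X).to_numpy(dtype=float)
        if self.add_intercept:
            Xa = np.column_stack([np.ones(len(Xa)), Xa])
        return Xa @ self.coef_


def fit_lmm(y, X, study_ids, **kwargs) -> RandomInterceptLMM:
    """Thin functional wrapper: fit a random-intercept LMM of effect sizes."""
    return RandomInterceptLMM(**kwargs).fit(X, y, groups=study_ids)


def vif(X: pd.DataFrame) -> VifReport:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j), from regressing
    each column on the others (with an intercept).  Perfectly collinear
    columns are reported as infinite."""
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two design columns")
    Xa = X.to_numpy(dtype=float)
    n = len(Xa)
    out: dict[str, float] = {}
    for j, name in enumerate(X.columns):
        target = Xa[:, j]
        others = np.column_stack(
            [np.ones(n), np.delete(Xa, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(((target - target.mean()) ** 2).sum())
        rss = float((resid ** 2).sum())
        if tss == 0.0:
            raise ValueError(f"column {name!r} is constant; VIF undefined")
        r2 = 1.0 - rss / tss
        out[name] = float("inf") if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return VifReport(vif=out, max_vif=max(out.values()))


__all__ = ["RandomInterceptLMM", "fit_lmm", "vif", "VifReport",
           "RankDeficientDesign"]
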