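"""Information-theoretic model selection and multimodel inference.

All-subsets enumeration over candidate fixed-effect terms, the
small-sample Akaike criterion

    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1),

Akaike weights exp(-delta/2) normalized over the candidate set, the
"best" set delta < 2, per-term variable importance (summed weights of
models containing the term), and natural model averaging: a coefficient is
averaged only over the models that contain it (weights renormalized over
that subset), avoiding shrinkage towards zero, with the Burnham-Anderson
unconditional standard error

    SE_u = sum_i w'_i * sqrt(se_i^2 + (theta_i - theta_bar)^2).

Multi-level factors enter or leave a model as whole terms (all their
contrast columns together), never column by column.

:class:`AICcModelAverager` is a scikit-learn style meta-estimator that runs
the whole procedure over any base estimator exposing ``loglik_``,
``n_params_``, ``nobs_``, ``coef_named_`` and ``bse_named_`` after ``fit``.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone


@dataclass(frozen=True)
class Term:
    """A candidate fixed-effect term and the design columns it owns."""

    name: str
    columns: tuple[str, ...]

    @classmethod
    def single(cls, name: str) -> "Term":
        return cls(name, (name,))


@dataclass
class FitSummary:
    """One fitted candidate model, ready for ranking and averaging."""

    terms: tuple[str, ...]
    loglik: float
    k: int
    n: int
    estimates: dict[str, tuple[float, float]]   # column -> (estimate, se)
    converged: bool = True
    aicc: float = field(default=float("nan"))
    delta: float = field(default=float("nan"))
    weight: float = field(default=float("nan"))

    def __post_init__(self):
        if np.isnan(self.aicc):
            self.aicc = aicc(self.loglik, self.k, self.n)

    @property
    def formula(self) -> str:
        return " + ".join(self.terms) if self.terms else "(null)"


@dataclass(frozen=True)
class AveragedEstimate:
    term: str
    estimate: float
    unconditional_se: float
    ci_low: float
    ci_high: float
    importance: float


def enumerate_subsets(terms: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^m subsets of candidate terms, null model first, in a
    deterministic order (bitmask over the input order)."""
    terms = list(terms)
    if len(set(terms)) != len(terms):
        raise ValueError(f"duplicate candidate terms: {terms}")
    subsets = []
    for mask in range(2 ** len(terms)):
        subsets.append(tuple(t for i, t in enumerate(terms) if mask >> i & 1))
    return subsets


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n}, k={k}: correction requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_and_weight(fits: Sequence[FitSummary]) -> list[FitSummary]:
    """Fill delta (AICc above the best model) and Akaike weight for every
    fit.  All fits must share the same sample size n."""
    fits = list(fits)
    if not fits:
        raise ValueError("cannot rank an empty collection of fits")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits have differing sample sizes {sorted(ns)}")
    best = min(f.aicc for f in fits)
    deltas = np.array([f.aicc - best for f in fits])
    raw = np.exp(-deltas / 2.0)
    weights = raw / raw.sum()
    return [replace(f, delta=float(d), weight=float(w))
            for f, d, w in zip(fits, deltas, weights)]


def best_set(fits: Sequence[FitSummary], threshold: float = 2.0) -> list[FitSummary]:
    """Models with delta below ``threshold`` (strict), sorted by delta."""
    ranked = [f for f in fits if f.delta < threshold]
    return sorted(ranked, key=lambda f: f.delta)


def importance(fits: Sequence[FitSummary], term: str) -> float:
    """Variable importance: sum of Akaike weights of models containing the
    term, over the full candidate set."""
    return float(sum(f.weight for f in fits if term in f.terms))


def natural_average(
    fits: Sequence[FitSummary],
    coefficient: str,
    term: str | None = None,
    z_crit: float = 1.96,
) -> AveragedEstimate:
    """Model-averaged coefficient by natural averaging.

    The estimate is averaged only over the models whose ``estimates``
    contain ``coefficient``, with Akaike weights renormalized over that
    subset; importance uses unrenormalized weights of models containing the
    parent ``term`` (defaults to the coefficient's name).
    """
    containing = [f for f in fits if coefficient in f.estimates]
    if not containing:
        raise ValueError(f"coefficient {coefficient!r} appears in no fitted model")
    w = np.array([f.weight for f in containing])
    w = w / w.sum()
    theta = np.array([f.estimates[coefficient][0] for f in containing])
    se = np.array([f.estimates[coefficient][1] for f in containing])
    est = float(w @ theta)
    unc_se = float(w @ np.sqrt(se**2 + (theta - est) ** 2))
    imp = importance(fits, term if term is not None else coefficient)
    return AveragedEstimate(
        term=coefficient,
        estimate=est,
        unconditional_se=unc_se,
        ci_low=est - z_crit * unc_se,
        ci_high=est + z_crit * unc_se,
        importance=imp,
    )


class AICcModelAverager(BaseEstimator):
    """All-subsets AICc model selection and natural averaging over a base
    estimator.

    Parameters
    ----------
    estimator : object
        A scikit-learn style estimator; after ``fit(X, y, **fit_params)``
        it must expose ``loglik_``, ``n_params_``, ``nobs_``,
        ``coef_named_`` (dict column -> estimate) and ``bse_named_``.
        It must accept a design with zero columns (the null model).
    terms : sequence of Term
        Candidate fixed-effect terms; each owns one or more columns of the
        design frame passed to :meth:`fit`.
    threshold : float, default 2.0
        Delta-AICc cutoff for the best set.

    Attributes
    ----------
    fits_ : list of FitSummary, ranked and weighted (converged fits only).
    best_set_ : list of FitSummary with delta < threshold, by delta.
    importance_ : dict term name -> summed Akaike weight.
    averaged_ : dict column name -> AveragedEstimate.
    n_candidates_ : number of candidate subsets enumerated (2^m).
    """

    def __init__(self, estimator, terms: Sequence[Term], threshold: float = 2.0):
        self.estimator = estimator
        self.terms = terms
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y, **fit_params):
        terms = list(self.terms)
        by_name = {t.name: t for t in terms}
        if len(by_name) != len(terms):
            raise ValueError("duplicate term names")
        subsets = enumerate_subsets([t.name for t in terms])
        self.n_candidates_ = len(subsets)

        fits: list[FitSummary] = []
        self.models_ = {}
        for subset in subsets:
            cols = [c for name in subset for c in by_name[name].columns]
            est = clone(self.estimator)
            est.fit(X.loc[:, cols], y, **fit_params)
            summary = FitSummary(
                terms=subset,
                loglik=float(est.loglik_),
                k=int(est.n_params_),
                n=int(est.nobs_),
                estimates={c: (float(est.coef_named_[c]), float(est.bse_named_[c]))
                           for c in cols},
                converged=bool(getattr(est, "converged_", True)),
            )
            fits.append(summary)
            self.models_[subset] = est

        converged = [f for f in fits if f.converged]
        dropped = len(fits) - len(converged)
        if dropped:
            warnings.warn(
                f"{dropped} candidate model(s) did not converge and were "
                "dropped from the averaging set", stacklevel=2)
        self.fits_ = rank_and_weight(converged)
        self.best_set_ = best_set(self.fits_, self.threshold)
        self.importance_ = {t.name: importance(self.fits_, t.name) for t in terms}
        self.averaged_ = {}
        for t in terms:
            for col in t.columns:
                avg = natural_average(self.fits_, col, term=t.name)
                self.averaged_[col] = avg
        return self

    def model_table(self) -> pd.DataFrame:
        """Ranked candidate models as a table (formula, parameters,
        log-likelihood, delta AICc, Akaike weight)."""
        rows = sorted(self.fits_, key=lambda f: f.delta)
        return pd.DataFrame(
            [
                {
                    "model": f.formula,
                    "parameters": f.k,
                    "log_likelihood": f.loglik,
                    "delta_aicc": f.delta,
                    "akaike_weight": f.weight,
                }
                for f in rows
            ]
        )

    def estimates_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": a.term,
                    "estimate": a.estimate,
                    "unconditional_se": a.unconditional_se,
                    "ci_low": a.ci_low,
                    "ci_high": a.ci_high,
                    "importance": a.importance,
                }
                for a in self.averaged_.values()
            ]
        )


__all__ = [
    "Term", "FitSummary", "AveragedEstimate", "enumerate_subsets", "aicc",
    "rank_and_weight", "best_set", "importance", "natural_average",
    "AICcModelAverager",
]
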