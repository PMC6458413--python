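"""Proportional-odds MLE: standardization, closed forms, oracles, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from camtrapmeta.modsel import AICcModelAverager
from camtrapmeta.ordinal import ProportionalOddsModel, odds_ratio
from camtrapmeta.pipeline import ORDINAL_TERMS
from camtrapmeta.records import StudyRecord
from camtrapmeta.standardize import TwoSDScaler, standardize


def _study(sid, lat, wt, rec="ambiguous", cam="digital"):
    return StudyRecord(sid, cam, "not_used", "closed", lat, wt, rec)


class TestStandardize:
    def test_two_point_latitude(self):
        d = standardize([_study("a", 10.0, np.e), _study("b", 30.0, np.e**3)])
        assert d.frame["latitude_std"].tolist() == pytest.approx([-0.5, 0.5])
        # weights are log-transformed first: log {e, e^3} = {1, 3}
        assert d.frame["log_min_weight_std"].tolist() == pytest.approx([-0.5, 0.5])

    def test_standardized_columns_have_mean_zero_sd_half(self, default_dataset):
        studies, _, _ = default_dataset
        d = standardize(studies)
        for col in ("latitude_std", "log_min_weight_std"):
            assert d.frame[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert d.frame[col].std(ddof=0) == pytest.approx(0.5, abs=1e-10)
        assert set(np.unique(d.frame[["film", "attractant_used",
                                      "habitat_open"]])) <= {0.0, 1.0}

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="variance"):
            standardize([_study("a", 10.0, 5.0), _study("b", 10.0, 7.0)])

    def test_scaler_stores_constants_for_later_use(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0, 6.0]})
        scaler = TwoSDScaler(columns=["x"]).fit(frame)
        out = scaler.transform(pd.DataFrame({"x": [3.0]}))
        assert out["x"].iloc[0] == pytest.approx(
            (3.0 - frame["x"].mean()) / (2 * frame["x"].std(ddof=0)))


class TestProportionalOddsFit:
    def test_intercept_only_matches_multinomial_closed_form(self):
        counts = {0: 17, 1: 41, 2: 46}
        y = np.repeat(list(counts), list(counts.values()))
        n = len(y)
        m = ProportionalOddsModel().fit(pd.DataFrame(index=range(n)), y)
        # fitted cumulative probabilities = empirical {17/104, 58/104}
        cum = expit(m.thresholds_)
        assert cum == pytest.approx([17 / 104, 58 / 104], abs=1e-8)
        closed_form = sum(c * np.log(c / n) for c in counts.values())
        assert m.loglik_ == pytest.approx(closed_form, abs=1e-8)
        assert m.converged_

    def test_no_slopes_means_identical_row_probabilities(self):
        y = np.array([0, 1, 2, 1, 2, 2, 0, 1])
        m = ProportionalOddsModel().fit(pd.DataFrame(index=range(8)), y)
        probs = m.predict_proba(pd.DataFrame(index=range(8)))
        assert np.ptp(probs, axis=0) == pytest.approx([0, 0, 0], abs=1e-12)
        assert probs.sum(axis=1) == pytest.approx(np.ones(8), abs=1e-12)

    def test_agrees_with_derivative_free_oracle_on_small_fixture(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame({"x1": rng.normal(size=12),
                          "x2": (rng.random(12) < 0.5).astype(float)})
        y = np.array([0, 1, 2, 2, 1, 0, 2, 1, 2, 0, 1, 2])
        m = ProportionalOddsModel().fit(X, y)

        def negll(params):
            t1, t2, b1, b2 = params
            if t2 <= t1:
                return 1e10
            eta = X["x1"].to_numpy() * b1 + X["x2"].to_numpy() * b2
            g1, g2 = expit(t1 - eta), expit(t2 - eta)
            P = np.stack([g1, g2 - g1, 1 - g2], 1)[np.arange(12), y]
            return -np.log(np.clip(P, 1e-300, None)).sum()

        best = min(
            minimize(negll, start, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12,
                              "maxiter": 20000, "maxfev": 20000}).fun
            for start in ([-0.5, 0.5, 0, 0], [-1, 1, 0.5, -0.5], [0, 1, 0, 0]))
        assert m.loglik_ == pytest.approx(-best, abs=1e-6)

    def test_agrees_with_statsmodels_ordered_model(self, default_dataset):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        studies, _, _ = default_dataset
        d = standardize(studies)
        mine = ProportionalOddsModel().fit(d.frame, d.response)
        ref = OrderedModel(d.response, d.frame.to_numpy(float),
                           distr="logit").fit(method="bfgs", disp=0)
        assert mine.loglik_ >= ref.llf - 1e-6
        assert np.abs(mine.coef_ - ref.params[:5]).max() < 1e-3
        assert np.abs(mine.bse_ - np.asarray(ref.bse[:5])).max() < 1e-3

    def test_parameter_recovery_from_proportional_odds_process(self):
        rng = np.random.default_rng(20260929)
        n, beta = 2000, np.array([1.2, -0.8, 0.45])
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        theta = np.array([-0.7, 0.7])
        cum = expit(theta[None, :] - (X.to_numpy() @ beta)[:, None])
        y = (rng.random(n)[:, None] > cum).sum(axis=1)
        m = ProportionalOddsModel().fit(X, y)
        assert np.abs(m.coef_ - beta).max() < 0.1

    def test_threshold_and_predictor_shift_invariance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = rng.integers(0, 3, size=50)
        m = ProportionalOddsModel().fit(X, y)
        base = m.predict_proba(X)
        # shifting every threshold and the linear predictor by c is a no-op
        c = 3.7
        eta = X["x"].to_numpy() * m.coef_[0] + c
        gamma = expit((m.thresholds_ + c)[None, :] - eta[:, None])
        shifted = np.diff(np.concatenate(
            [np.zeros((50, 1)), gamma, np.ones((50, 1))], axis=1))
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_unstandardized_fit_is_equivalent(self):
        rng = np.random.default_rng(8)
        raw = pd.DataFrame({"x": rng.normal(10, 3, size=200)})
        y = (rng.random(200)[:, None] >
             expit(np.array([[-0.5, 0.8]]) - 0.3 * (raw[["x"]].to_numpy() - 10))
             ).sum(axis=1)
        sd2 = 2 * raw["x"].std(ddof=1)
        std = (raw - raw["x"].mean()) / sd2
        m_raw = ProportionalOddsModel().fit(raw, y)
        m_std = ProportionalOddsModel().fit(std, y)
        assert m_raw.loglik_ == pytest.approx(m_std.loglik_, abs=1e-8)
        assert m_std.coef_[0] == pytest.approx(m_raw.coef_[0] * sd2, rel=1e-5)

    def test_two_slope_model_counts_four_parameters(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = rng.integers(0, 3, size=60)
        m = ProportionalOddsModel().fit(X, y)
        assert m.n_params_ == 4  # 2 slopes + 2 thresholds

    def test_complete_separation_is_flagged_not_fatal(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10), 2 * np.ones(10)]})
        y = np.r_[np.zeros(10), np.ones(10), 2 * np.ones(10)].astype(int)
        m = ProportionalOddsModel().fit(X, y)
        assert not m.converged_


class TestOddsRatio:
    @pytest.mark.parametrize("estimate, expected", [
        (-1.42, 4.137), (0.0, 1.0), (-0.94, 2.56)])
    def test_reference_level_odds_ratios(self, estimate, expected):
        assert odds_ratio(estimate) == pytest.approx(expected, abs=5e-3)

    def test_published_rounding_convention(self):
        assert round(odds_ratio(-1.42), 1) == 4.1


class TestAllSubsetsIntegration:
    def test_averager_enumerates_32_candidates_and_averages(self, default_dataset):
        studies, _, _ = default_dataset
        d = standardize(studies)
        avg = AICcModelAverager(ProportionalOddsModel(), ORDINAL_TERMS)
        avg.fit(d.frame, d.response)
        assert avg.n_candidates_ == 32
        assert sum(f.weight for f in avg.fits_) == pytest.approx(1.0, abs=1e-12)
        assert min(f.delta for f in avg.fits_) == 0.0
        # null model contributes 2 threshold parameters
        null = next(f for f in avg.fits_ if f.terms == ())
        assert null.k == 2
        film = avg.averaged_["film"]
        assert film.ci_low < film.estimate < film.ci_high
        assert 0.0 <= avg.importance_["camera_type"] <= 1.0
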