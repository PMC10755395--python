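"""Bland-Altman machinery: classic, log-regression, prediction, correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from basketintake.agreement import (
    ClassicBlandAltman,
    LogRatioAgreement,
    agreement_by_measure,
    classic_ba,
    default_measures,
    log_ba_regression,
    pearson_r,
    predict_ratio,
    ratio_unity_point,
)
from basketintake.errors import (
    DataError,
    InsufficientDataError,
    SingularDesignError,
    UndefinedCorrelationError,
)


def ols_normal_equations(x, y):
    """Independent closed-form oracle: (X'X)^-1 X'y and n-2 residual sd."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s = math.sqrt(float(resid @ resid) / (len(x) - 2)) if len(x) > 2 else 0.0
    return float(beta[0]), float(beta[1]), s


def pairs_from_md(m, d):
    """Invert (mean-of-logs, log-difference) to the (P, I) pair."""
    m = np.asarray(m, float)
    d = np.asarray(d, float)
    return np.exp(m + d / 2), np.exp(m - d / 2)


class TestClassicBA:
    def test_perfect_agreement(self):
        res = classic_ba([100, 200, 300], [100, 200, 300])
        assert res.mean_diff == 0 and res.loa_lo == 0 and res.loa_hi == 0

    def test_hand_computed_oracle(self):
        """P=(110,190,310), I=(100,200,300): mean 3.333, sd 11.547."""
        res = classic_ba([110, 190, 310], [100, 200, 300])
        sd = math.sqrt(400 / 3)  # differences (10, -10, 10), n-1 denominator
        assert res.mean_diff == pytest.approx(10 / 3)
        assert res.sd_diff == pytest.approx(sd, rel=1e-12)
        assert res.sd_diff == pytest.approx(11.547, abs=5e-4)
        assert res.loa_lo == pytest.approx(10 / 3 - 1.96 * sd, rel=1e-12)
        assert res.loa_hi == pytest.approx(10 / 3 + 1.96 * sd, rel=1e-12)
        assert res.n == 3

    def test_translation_equivariance(self):
        P = np.array([120.0, 250.0, 330.0, 180.0])
        I = np.array([100.0, 240.0, 300.0, 200.0])
        base = classic_ba(P, I)
        shifted = classic_ba(P + 57.0, I)
        assert shifted.mean_diff == pytest.approx(base.mean_diff + 57.0)
        assert shifted.loa_lo == pytest.approx(base.loa_lo + 57.0)
        assert shifted.loa_hi == pytest.approx(base.loa_hi + 57.0)
        assert shifted.sd_diff == pytest.approx(base.sd_diff)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            classic_ba([1.0], [2.0])


class TestLogBARegression:
    def test_exact_linear_fit(self):
        """d = 0.1*m - 0.8 exactly -> beta recovered, zero residual sd."""
        m = np.array([6.0, 7, 8, 9, 10])
        d = 0.1 * m - 0.8
        fit = log_ba_regression(*pairs_from_md(m, d))
        assert fit.beta1 == pytest.approx(0.1, abs=1e-10)
        assert fit.beta0 == pytest.approx(-0.8, abs=1e-10)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-10)

    def test_five_point_hand_oracle(self):
        """m=(6..10), d=(0,-0.1,0,0.1,0): beta1=0.02, beta0=-0.16,
        s=sqrt(0.016/3)=0.07303."""
        m = np.array([6.0, 7, 8, 9, 10])
        d = np.array([0.0, -0.1, 0, 0.1, 0])
        fit = log_ba_regression(*pairs_from_md(m, d))
        assert fit.beta1 == pytest.approx(0.02, abs=1e-9)
        assert fit.beta0 == pytest.approx(-0.16, abs=1e-9)
        assert fit.resid_sd == pytest.approx(math.sqrt(0.016 / 3), abs=1e-9)
        assert fit.n == 5

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        m = rng.normal(7.5, 0.4, size=40)
        d = 0.5 - 0.1 * m + rng.normal(0, 0.2, size=40)
        P, I = pairs_from_md(m, d)
        fit = log_ba_regression(P, I)
        b0, b1, s = ols_normal_equations(m, d)
        assert fit.beta0 == pytest.approx(b0, abs=1e-10)
        assert fit.beta1 == pytest.approx(b1, abs=1e-10)
        assert fit.resid_sd == pytest.approx(s, abs=1e-10)

    def test_parameter_recovery_large_n(self):
        """Simulated d = b0 + b1*m + N(0, sigma) at n=5000: estimates
        within 3 SE, residual sd within 5% of sigma."""
        rng = np.random.default_rng(7)
        b0, b1, sigma = 2.0, -0.25, 0.3
        m = rng.normal(7.6, 0.4, size=5000)
        d = b0 + b1 * m + rng.normal(0, sigma, size=5000)
        est = LogRatioAgreement().fit(*pairs_from_md(m, d))
        assert abs(est.beta0_ - b0) < 3 * est.beta0_se_
        assert abs(est.beta1_ - b1) < 3 * est.beta1_se_
        assert abs(est.resid_sd_ - sigma) / sigma < 0.05

    def test_nonpositive_pairs_excluded_and_counted(self):
        P = [100.0, 200, 0.0, 300, 400]
        I = [110.0, 190, 150, -1.0, 380]
        fit = log_ba_regression(P, I)
        assert fit.excluded_nonpositive == 2
        assert fit.n == 3

    def test_singular_design(self):
        # all mean-of-logs identical: P*I constant
        with pytest.raises(SingularDesignError):
            log_ba_regression([2.0, 4.0, 8.0], [8.0, 4.0, 2.0])

    def test_insufficient_valid_pairs(self):
        with pytest.raises(InsufficientDataError):
            log_ba_regression([1.0, 2.0, -1.0], [1.0, 2.0, 3.0])

    def test_swap_antisymmetry(self):
        """Exchanging P and I negates beta0 and beta1, keeps s, and
        inverts the predicted ratio."""
        rng = np.random.default_rng(3)
        m = rng.normal(7.5, 0.5, size=30)
        d = 1.2 - 0.2 * m + rng.normal(0, 0.15, size=30)
        P, I = pairs_from_md(m, d)
        f = log_ba_regression(P, I)
        g = log_ba_regression(I, P)
        assert g.beta0 == pytest.approx(-f.beta0, abs=1e-10)
        assert g.beta1 == pytest.approx(-f.beta1, abs=1e-10)
        assert g.resid_sd == pytest.approx(f.resid_sd, abs=1e-10)
        rf = predict_ratio(f, 2000.0)
        rg = predict_ratio(g, 2000.0)
        assert rg.ratio == pytest.approx(1 / rf.ratio, rel=1e-10)
        assert rg.loa_lo_ratio == pytest.approx(1 / rf.loa_hi_ratio, rel=1e-10)

    def test_units_invariance(self):
        """Scaling both measures by c leaves beta1 and s unchanged and
        shifts beta0 by (1 - beta1) * ln(c) along the m axis."""
        rng = np.random.default_rng(5)
        m = rng.normal(7.5, 0.5, size=50)
        d = 0.8 - 0.15 * m + rng.normal(0, 0.1, size=50)
        P, I = pairs_from_md(m, d)
        c = 4.184  # kcal -> kJ
        f = log_ba_regression(P, I)
        g = log_ba_regression(c * P, c * I)
        assert g.beta1 == pytest.approx(f.beta1, abs=1e-10)
        assert g.resid_sd == pytest.approx(f.resid_sd, abs=1e-10)
        assert g.beta0 == pytest.approx(f.beta0 - f.beta1 * math.log(c), abs=1e-10)
        # the fitted ratio at magnitude c*A equals the original at A
        assert predict_ratio(g, c * 2000).ratio == pytest.approx(
            predict_ratio(f, 2000).ratio, rel=1e-10
        )


class TestPredictRatio:
    def test_perfect_agreement_identity(self):
        est = LogRatioAgreement()
        est.beta0_, est.beta1_, est.resid_sd_ = 0.0, 0.0, 0.0
        pred = est.predict_ratio(1234.5)
        assert (pred.ratio, pred.loa_lo_ratio, pred.loa_hi_ratio) == (1.0, 1.0, 1.0)

    def test_ln_2000_constant(self):
        assert round(math.log(2000), 1) == 7.6

    def test_hand_arithmetic_oracle(self):
        """beta0=2, beta1=-0.25, s=0.3 at A=2000 -> ratio 1.105,
        LoA (0.614, 1.989)."""
        est = LogRatioAgreement()
        est.beta0_, est.beta1_, est.resid_sd_ = 2.0, -0.25, 0.3
        pred = est.predict_ratio(2000.0)
        assert pred.ratio == pytest.approx(1.105, abs=5e-4)
        assert pred.loa_lo_ratio == pytest.approx(0.614, abs=5e-4)
        assert pred.loa_hi_ratio == pytest.approx(1.989, abs=5e-4)

    def test_domain_error(self):
        est = LogRatioAgreement()
        est.beta0_, est.beta1_, est.resid_sd_ = 0.0, 0.0, 0.0
        with pytest.raises(DataError):
            est.predict_ratio(0.0)

    def test_ratio_unity_point(self):
        """A* = exp(-beta0/beta1): with beta0=0.5, beta1=-0.152,
        exp(3.289) = 26.83."""
        est = LogRatioAgreement()
        est.beta0_, est.beta1_, est.resid_sd_ = 0.5, -0.152, 0.1
        assert est.ratio_unity_point() == pytest.approx(26.83, abs=5e-2)
        assert est.predict_ratio(est.ratio_unity_point()).ratio == pytest.approx(1.0)
        est.beta1_ = 0.0
        assert est.ratio_unity_point() is None

    def test_functional_wrapper_matches(self):
        fit = log_ba_regression([110.0, 205, 290, 420], [100.0, 210, 300, 400])
        pred = predict_ratio(fit, 250.0)
        est = LogRatioAgreement().fit([110.0, 205, 290, 420], [100.0, 210, 300, 400])
        pred2 = est.predict_ratio(250.0)
        assert pred == pred2
        assert ratio_unity_point(fit) == est.ratio_unity_point()


class TestPearson:
    def test_proportional_measures(self):
        I = np.array([100.0, 200, 300, 400])
        assert pearson_r(2 * I, I) == pytest.approx(1.0)

    def test_perfect_negative(self):
        I = np.array([1.0, 2, 3, 4])
        assert pearson_r(-I + 10, I) == pytest.approx(-1.0)

    def test_fixed_six_points_against_numpy(self):
        P = np.array([2300.0, 1500, 3200, 900, 2100, 2700])
        I = np.array([2000.0, 1800, 2500, 1200, 2050, 2400])
        expected = float(np.corrcoef(P, I)[0, 1])
        assert pearson_r(P, I) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLoACoverage:
    def test_gaussian_residual_coverage(self):
        """With Gaussian residuals the +/-1.96 s band around the fitted
        line contains ~95% of points (n=5000)."""
        rng = np.random.default_rng(11)
        m = rng.normal(7.6, 0.5, size=5000)
        d = 1.0 - 0.2 * m + rng.normal(0, 0.4, size=5000)
        est = LogRatioAgreement().fit(*pairs_from_md(m, d))
        line = est.beta0_ + est.beta1_ * est.m_
        inside = np.abs(est.d_ - line) <= 1.96 * est.resid_sd_
        assert inside.mean() == pytest.approx(0.95, abs=0.015)


class TestSklearnCompat:
    def test_get_params_and_clone(self):
        est = LogRatioAgreement(loa_multiplier=2.0)
        assert est.get_params() == {"loa_multiplier": 2.0}
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        assert clone(ClassicBlandAltman()).get_params() == {"loa_multiplier": 1.96}

    def test_predict_is_vectorised(self):
        est = LogRatioAgreement()
        est.beta0_, est.beta1_, est.resid_sd_ = 0.5, -0.1, 0.2
        out = est.predict([100.0, 2000.0])
        assert out.shape == (2,)
        assert out[1] == pytest.approx(math.exp(0.5 - 0.1 * math.log(2000)))


class TestAgreementByMeasure:
    def test_pooled_count_is_17(self, small_report):
        """6 absolute analytes at 2 purchase levels + 5 relative = 17."""
        assert len(default_measures()) == 17
        assert len(small_report.agreement_pooled) == 17

    def test_beta1_zero_a_star_absent(self):
        rng = np.random.default_rng(2)
        m = rng.normal(7.5, 0.3, 200)
        d = np.zeros(200)
        P, I = pairs_from_md(m, d)
        df = pd.DataFrame({"purchase": P, "intake": I})
        out = agreement_by_measure(df, measures=[("flat", "purchase", "intake")])
        assert np.isnan(out.loc[0, "A_star"]) or out.loc[0, "beta1"] != 0

    def test_small_group_skipped_with_warning(self, caplog):
        df = pd.DataFrame(
            {
                "P": [100.0, 120, 130, 90],
                "I": [110.0, 115, 120, 100],
                "g": ["a", "a", "a", "b"],
            }
        )
        with caplog.at_level("WARNING"):
            out = agreement_by_measure(df, measures=[("x", "P", "I")], group_by="g")
        assert set(out["group"]) == {"a"}
        assert any("skipping" in rec.message for rec in caplog.records)
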