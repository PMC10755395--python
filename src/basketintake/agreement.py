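"""Bland-Altman agreement machinery.

Method-comparison statistics between a purchase-derived estimate P and
a self-reported intake estimate I for the same measure:

* :class:`ClassicBlandAltman` — mean difference (bias) and limits of
  agreement (LoA) at bias +/- 1.96 sd of the differences.
* :class:`LogRatioAgreement` — the regression approach on the log
  scale. Both values are log-transformed (heteroskedasticity: the
  spread and direction of differences grow with the magnitude of the
  mean), the difference d = ln P - ln I is regressed on the mean
  m = (ln P + ln I)/2 by OLS, and LoA are drawn at +/- 1.96 residual
  sd about the fitted line. Back-transforming gives the purchase:intake
  ratio at any chosen magnitude A, with multiplicative LoA.

Both are scikit-learn style estimators (``fit``/``predict``, fitted
attributes with trailing underscores, ``get_params``) so they compose
with sklearn tooling; the module-level functions are thin wrappers
returning frozen result dataclasses.

Conventions fixed here: the difference/ratio is always purchase minus
(or over) intake; 1.96 is used literally rather than a t-quantile; the
residual sd uses the n-2 regression denominator; pairs with a
non-positive value on either side are excluded from log-scale analyses
and counted. Prediction at A plugs ln(A) into the fitted line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    DataError,
    InsufficientDataError,
    SingularDesignError,
    UndefinedCorrelationError,
)
from .nutrients import NUTRIENT_FIELDS, RelativeProfile

logger = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class ClassicBA:
    """Classic Bland-Altman summary on the original measurement scale."""

    mean_diff: float
    sd_diff: float
    loa_lo: float
    loa_hi: float
    n: int


@dataclass(frozen=True)
class AgreementFit:
    """Log-scale difference-on-mean regression: d = beta0 + beta1 * m."""

    beta0: float
    beta1: float
    resid_sd: float
    n: int
    excluded_nonpositive: int = 0


@dataclass(frozen=True)
class RatioPrediction:
    """Back-transformed purchase:intake ratio and LoA at magnitude A."""

    A: float
    ratio: float
    loa_lo_ratio: float
    loa_hi_ratio: float


def _paired_arrays(P, I) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float).ravel()
    I = np.asarray(I, dtype=float).ravel()
    if P.shape != I.shape:
        raise DataError(f"P and I must have equal length, got {P.shape} vs {I.shape}")
    ok = np.isfinite(P) & np.isfinite(I)
    return P[ok], I[ok]


class ClassicBlandAltman(BaseEstimator):
    """Classic Bland-Altman bias and limits of agreement.

    Parameters
    ----------
    loa_multiplier : float, default 1.96
        Multiplier on the sd of differences for the LoA.

    Attributes (after ``fit``)
    --------------------------
    mean_diff_, sd_diff_, loa_lo_, loa_hi_, n_
    """

    def __init__(self, loa_multiplier: float = LOA_MULTIPLIER):
        self.loa_multiplier = loa_multiplier

    def fit(self, P, I) -> "ClassicBlandAltman":
        P, I = _paired_arrays(P, I)
        if P.size < 2:
            raise InsufficientDataError(f"classic Bland-Altman needs >= 2 pairs, got {P.size}")
        d = P - I
        self.mean_diff_ = float(np.mean(d))
        self.sd_diff_ = float(np.std(d, ddof=1))
        half = self.loa_multiplier * self.sd_diff_
        self.loa_lo_ = self.mean_diff_ - half
        self.loa_hi_ = self.mean_diff_ + half
        self.n_ = int(P.size)
        return self

    def result_(self) -> ClassicBA:
        return ClassicBA(self.mean_diff_, self.sd_diff_, self.loa_lo_, self.loa_hi_, self.n_)


class LogRatioAgreement(BaseEstimator):
    """Regression-approach Bland-Altman on the log scale.

    ``fit(P, I)`` regresses d = ln P - ln I on m = (ln P + ln I)/2 by
    ordinary least squares; ``predict(A)`` returns the back-transformed
    purchase:intake ratio at magnitude A (original units), and
    ``predict_ratio(A)`` additionally carries the multiplicative LoA at
    ratio * exp(-/+ 1.96 s).

    Attributes (after ``fit``)
    --------------------------
    beta0_ : float       intercept, log-difference units
    beta1_ : float       slope per unit mean-of-logs
    resid_sd_ : float    residual sd, n-2 denominator
    n_ : int             pairs used (both values > 0)
    excluded_nonpositive_ : int
    beta0_se_, beta1_se_ : float   OLS standard errors
    """

    def __init__(self, loa_multiplier: float = LOA_MULTIPLIER):
        self.loa_multiplier = loa_multiplier

    def fit(self, P, I) -> "LogRatioAgreement":
        P, I = _paired_arrays(P, I)
        valid = (P > 0) & (I > 0)
        self.excluded_nonpositive_ = int((~valid).sum())
        P, I = P[valid], I[valid]
        n = P.size
        if n < 3:
            raise InsufficientDataError(
                f"log-scale agreement regression needs >= 3 positive pairs, got {n}"
            )
        lp, li = np.log(P), np.log(I)
        d = lp - li
        m = (lp + li) / 2.0
        mx = m - m.mean()
        sxx = float(mx @ mx)
        if sxx <= 0 or not np.isfinite(sxx):
            raise SingularDesignError("all mean-of-log values identical; slope is undefined")
        import statsmodels.api as sm

        ols = sm.OLS(d, sm.add_constant(m)).fit()
        self.beta0_ = float(ols.params[0])
        self.beta1_ = float(ols.params[1])
        self.beta0_se_ = float(ols.bse[0])
        self.beta1_se_ = float(ols.bse[1])
        self.resid_sd_ = float(np.sqrt(ols.ssr / (n - 2)))
        self.n_ = int(n)
        self.m_ = m
        self.d_ = d
        return self

    # -- prediction -------------------------------------------------------

    def predict(self, A) -> np.ndarray:
        """Purchase:intake ratio at magnitude(s) A (original units)."""
        A = np.asarray(A, dtype=float)
        if np.any(A <= 0):
            raise DataError("prediction magnitude A must be > 0")
        return np.exp(self.beta0_ + self.beta1_ * np.log(A))

    def predict_ratio(self, A: float) -> RatioPrediction:
        """Ratio and multiplicative LoA at one magnitude A."""
        if not A > 0:
            raise DataError(f"prediction magnitude A must be > 0, got {A!r}")
        dhat = self.beta0_ + self.beta1_ * math.log(A)
        half = self.loa_multiplier * self.resid_sd_
        return RatioPrediction(
            A=float(A),
            ratio=math.exp(dhat),
            loa_lo_ratio=math.exp(dhat - half),
            loa_hi_ratio=math.exp(dhat + half),
        )

    def ratio_unity_point(self) -> float | None:
        """A* where the fitted ratio equals 1: exp(-beta0/beta1).

        None when beta1 == 0 (the fitted ratio never crosses 1 unless
        it is identically 1).
        """
        if self.beta1_ == 0:
            return None
        return float(math.exp(-self.beta0_ / self.beta1_))

    def result_(self) -> AgreementFit:
        return AgreementFit(
            beta0=self.beta0_,
            beta1=self.beta1_,
            resid_sd=self.resid_sd_,
            n=self.n_,
            excluded_nonpositive=self.excluded_nonpositive_,
        )


# ---------------------------------------------------------------------------
# Thin functional wrappers


def classic_ba(P, I) -> ClassicBA:
    return ClassicBlandAltman().fit(P, I).result_()


def log_ba_regression(P, I) -> AgreementFit:
    return LogRatioAgreement().fit(P, I).result_()


def predict_ratio(fit: AgreementFit, A: float, loa_multiplier: float = LOA_MULTIPLIER) -> RatioPrediction:
    if not A > 0:
        raise DataError(f"prediction magnitude A must be > 0, got {A!r}")
    dhat = fit.beta0 + fit.beta1 * math.log(A)
    half = loa_multiplier * fit.resid_sd
    return RatioPrediction(float(A), math.exp(dhat), math.exp(dhat - half), math.exp(dhat + half))


def ratio_unity_point(fit: AgreementFit) -> float | None:
    if fit.beta1 == 0:
        return None
    return float(math.exp(-fit.beta0 / fit.beta1))


def pearson_r(P, I) -> float:
    """Product-moment correlation between the paired measures."""
    P, I = _paired_arrays(P, I)
    if P.size < 3:
        raise InsufficientDataError(f"correlation needs >= 3 pairs, got {P.size}")
    if np.std(P) == 0 or np.std(I) == 0:
        raise UndefinedCorrelationError("correlation undefined when a measure has zero variance")
    return float(stats.pearsonr(P, I).statistic)


# ---------------------------------------------------------------------------
# Measure-by-measure agreement tables

#: (measure key, purchase column, intake column) for absolute measures at
#: both purchase levels and the five relative measures.
ABSOLUTE_LEVELS = ("household", "individual")


def default_measures() -> list[tuple[str, str, str]]:
    """The 17 pooled measures: 6 analytes x 2 purchase levels + 5 relative."""
    measures = []
    for level in ABSOLUTE_LEVELS:
        for f in NUTRIENT_FIELDS:
            measures.append((f"{level}:{f}", f"{level}_{f}", f"intake_{f}"))
    for r in RelativeProfile.MEASURES:
        measures.append((f"relative:{r}", f"purchase_{r}", f"intake_{r}"))
    return measures


def agreement_by_measure(
    data: pd.DataFrame,
    measures: list[tuple[str, str, str]] | None = None,
    group_by: str | None = None,
    A_kcal: float = 2000.0,
) -> pd.DataFrame:
    """One log-scale agreement fit per (measure, group).

    ``data`` holds one row per participant with purchase and intake
    columns for every measure (see :func:`default_measures`) and, when
    ``group_by`` is given, that grouping column. Energy measures are
    additionally predicted at ``A_kcal``; every measure is predicted at
    the geometric mean of its realized mean-of-measures and, when the
    slope is non-zero, reports the ratio-unity point A*. Groups with
    fewer than 3 valid pairs are skipped with a warning.
    """
    if measures is None:
        measures = default_measures()
    if group_by is None:
        groups = [("pooled", data)]
    else:
        groups = list(data.groupby(group_by, sort=True))
    rows = []
    for gname, gdata in groups:
        for key, pcol, icol in measures:
            P = gdata[pcol].to_numpy(float)
            I = gdata[icol].to_numpy(float)
            try:
                est = LogRatioAgreement().fit(P, I)
            except (InsufficientDataError, SingularDesignError) as exc:
                logger.warning("skipping measure %s in group %s: %s", key, gname, exc)
                continue
            is_energy = key.endswith(":energy_kcal")
            A = A_kcal if is_energy else float(np.exp(np.mean(est.m_)))
            pred = est.predict_ratio(A)
            a_star = est.ratio_unity_point()
            rows.append(
                {
                    "measure": key,
                    "group": str(gname),
                    "n": est.n_,
                    "excluded_nonpositive": est.excluded_nonpositive_,
                    "beta0": est.beta0_,
                    "beta1": est.beta1_,
                    "resid_sd": est.resid_sd_,
                    "A": pred.A,
                    "ratio_at_A": pred.ratio,
                    "loa_lo_at_A": pred.loa_lo_ratio,
                    "loa_hi_at_A": pred.loa_hi_ratio,
                    "A_star": a_star if a_star is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
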