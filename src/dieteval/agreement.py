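"""Regression-based agreement between tool and gold standard, per nutrient.

Instead of a Bland–Altman analysis (biased when one method is nearly
error-free), the tool's measurements ``y`` are regressed on the gold-standard
values ``x``:

    y = alpha + beta * x + sigma(x) * eps,      eps ~ N(0, 1)

``alpha`` is the differential bias (units of the nutrient), ``beta`` the
proportional bias (1 = no proportional error).  Heteroscedasticity is modeled
with a standard deviation linear in the true value, ``sigma(x) = s0 + s1*x``,
estimated by regressing absolute OLS residuals on x and scaling by
sqrt(pi/2) (the normality correction E|eps| = sqrt(2/pi)).  The 95% limits of
agreement are the untransformed Wald band ``alpha + beta*x +/- 1.96*sigma(x)``;
the coefficient of variation is ``Cv(x) = sigma(x) / (alpha + beta*x)``.

Alternative variance families (power-of-x, exponential) can be swapped in via
``fit_variance(..., family=...)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AgreementFit",
    "CvSummary",
    "fit_calibration",
    "fit_variance",
    "fit_agreement",
    "limits_of_agreement",
    "cv_summary",
]

_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


@dataclass
class AgreementFit:
    """Mean and variance model of one nutrient's tool-vs-reference agreement."""

    nutrient: str
    alpha: float  # differential bias (intercept), nutrient units
    beta: float  # proportional bias (slope), dimensionless
    alpha_se: float
    beta_se: float
    s0: float  # sigma(x) intercept
    s1: float  # sigma(x) slope
    sigma_floor: float
    n: int
    residuals: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)

    def predict(self, x) -> np.ndarray:
        return self.alpha + self.beta * np.asarray(x, dtype=float)

    def sigma(self, x) -> np.ndarray:
        """Modeled SD of tool measurements at true value x, floored above zero."""
        raw = self.s0 + self.s1 * np.asarray(x, dtype=float)
        return np.maximum(raw, self.sigma_floor)


def fit_calibration(
    x: Sequence[float], y: Sequence[float], nutrient: str = ""
) -> AgreementFit:
    """OLS of tool values on gold-standard values; returns the mean-part fit.

    The variance parameters are initialised to zero; chain with
    :func:`fit_variance` (or use :func:`fit_agreement`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("calibration fit needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; proportional bias is unidentifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    alpha, beta = model.params
    alpha_se, beta_se = model.bse
    floor = 1e-6 * max(np.abs(y).max(), 1.0)
    return AgreementFit(
        nutrient=nutrient,
        alpha=float(alpha),
        beta=float(beta),
        alpha_se=float(alpha_se),
        beta_se=float(beta_se),
        s0=0.0,
        s1=0.0,
        sigma_floor=floor,
        n=x.size,
        residuals=np.asarray(model.resid),
        x=x,
    )


def fit_variance(
    x: Sequence[float],
    residuals: Sequence[float],
    fit: Optional[AgreementFit] = None,
    family: str = "linear",
) -> tuple[float, float]:
    """Estimate the variance-function parameters from calibration residuals.

    ``linear`` (default): regress |residual| on x and scale both coefficients
    by sqrt(pi/2), giving sigma(x) = s0 + s1*x.  ``power``: sigma(x) =
    s0 * (1+x)^s1 via the same regression on log scale.  If the fitted sigma
    is non-positive over more than 10% of the observed x range a warning is
    emitted and evaluation relies on the floor.  Updates ``fit`` in place when
    given.
    """
    x = np.asarray(x, dtype=float)
    r = np.abs(np.asarray(residuals, dtype=float))
    if x.shape != r.shape:
        raise ValueError("x and residuals must have equal length")
    if family == "linear":
        coef = sm.OLS(r, sm.add_constant(x)).fit().params
        s0, s1 = (float(c) * _SQRT_HALF_PI for c in coef)
    elif family == "power":
        logr = np.log(np.maximum(r, 1e-12))
        coef = sm.OLS(logr, sm.add_constant(np.log1p(x))).fit().params
        s0, s1 = float(np.exp(coef[0]) * _SQRT_HALF_PI), float(coef[1])
    else:
        raise ValueError(f"unknown variance family {family!r}")

    if family == "linear":
        grid = np.linspace(x.min(), x.max(), 101)
        if np.mean(s0 + s1 * grid <= 0) > 0.10:
            warnings.warn(
                "fitted sigma(x) non-positive over >10% of the x range; the floor applies"
            )
    if fit is not None:
        fit.s0, fit.s1 = s0, s1
    return s0, s1


def fit_agreement(x: Sequence[float], y: Sequence[float], nutrient: str = "") -> AgreementFit:
    """Single-pass mean + variance fit (OLS, then absolute-residual regression)."""
    fit = fit_calibration(x, y, nutrient=nutrient)
    fit_variance(fit.x, fit.residuals, fit=fit)
    return fit


def limits_of_agreement(fit: AgreementFit, x_grid: Sequence[float]) -> pd.DataFrame:
    """Untransformed Wald 95% limits: (alpha + beta*x) +/- 1.96*sigma(x).

    No transformation is applied, so with a large sigma the lower limit can
    cross zero for a non-negative nutrient (as happens for alcohol) — itself a
    sign of very poor agreement.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    center = fit.predict(x_grid)
    half = 1.96 * fit.sigma(x_grid)
    return pd.DataFrame(
        {"x": x_grid, "center": center, "lower": center - half, "upper": center + half}
    )


@dataclass(frozen=True)
class CvSummary:
    nutrient: str
    stratum: str  # all | foods | beverages
    cv_q25: float
    cv_median: float
    cv_q75: float
    mean_cv: float
    n: int
    n_excluded: int  # records where the modeled mean was <= 0


def cv_summary(fit: AgreementFit, x: Sequence[float], stratum: str = "all") -> CvSummary:
    """Coefficient of variation at the quartiles of x, and its mean over records.

    Cv(x) = sigma(x)/(alpha + beta*x), evaluated at the 25th/50th/75th
    linear-interpolation percentiles of the stratum's true values; the mean Cv
    averages Cv(x_i) over records, excluding (and counting) records where the
    modeled mean is non-positive.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cv_summary needs at least one record")
    q25, med, q75 = np.percentile(x, [25, 50, 75])

    def _cv(v: np.ndarray) -> np.ndarray:
        mean = fit.predict(v)
        out = np.full(v.shape, np.nan)
        ok = mean > 0
        out[ok] = fit.sigma(v[ok]) / mean[ok]
        return out

    cv_points = _cv(np.array([q25, med, q75]))
    per_record = _cv(x)
    ok = ~np.isnan(per_record)
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("all records excluded: modeled mean non-positive everywhere")
    return CvSummary(
        nutrient=fit.nutrient,
        stratum=stratum,
        cv_q25=float(cv_points[0]),
        cv_median=float(cv_points[1]),
        cv_q75=float(cv_points[2]),
        mean_cv=float(per_record[ok].mean()),
        n=x.size,
        n_excluded=n_excluded,
    )
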