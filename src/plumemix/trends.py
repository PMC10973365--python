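"""Annual-mean temporal trend fits with autocorrelation diagnostics.

Trend regressions are ordinary least squares of annual means on elapsed
years, with 1985 as year zero so intercepts are concentrations at the start
of the study window. Residual autocorrelation is diagnosed with the
Durbin-Watson statistic; when significant, the fit is repeated after an
iterative Cochrane-Orcutt quasi-differencing transform. Heteroscedasticity
is diagnosed with the Breusch-Pagan test.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .errors import InsufficientDataError

__all__ = [
    "TrendResult", "annual_means", "ols_trend", "durbin_watson",
    "dw_decision", "cochrane_orcutt", "breusch_pagan", "fit_trend",
]

YEAR_ZERO = 1985


@dataclass
class TrendResult:
    """One annual-mean-vs-time regression with its diagnostics.

    ``slope``/``intercept`` are the uncorrected OLS fit with the intercept at
    year zero; the ``corrected_*`` fields hold the Cochrane-Orcutt fit
    transformed back to the original scale when a correction was run.
    """

    variable: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_years: int
    slope_se: float = np.nan
    dw_stat: float = np.nan
    dw_significant: bool = False
    bp_stat: float = np.nan
    bp_p: float = np.nan
    rho_hat: float = np.nan
    corrected: bool = False
    corrected_slope: float = np.nan
    corrected_slope_se: float = np.nan
    corrected_intercept: float = np.nan
    corrected_p: float = np.nan
    co_converged: bool = True

    @property
    def significant(self) -> bool:
        p = self.corrected_p if self.corrected else self.p_value
        return bool(p < 0.05)

    def to_dict(self) -> dict:
        return asdict(self)


def annual_means(samples: pd.DataFrame, variable: str,
                 date_col: str = "date") -> pd.DataFrame:
    """Arithmetic mean of ``variable`` per calendar year.

    Returns a DataFrame (year, value, n) sorted by year; years without
    samples are simply absent.
    """
    dates = pd.to_datetime(samples[date_col])
    grouped = samples.groupby(dates.dt.year)[variable]
    out = pd.DataFrame({"year": grouped.mean().index,
                        "value": grouped.mean().to_numpy(),
                        "n": grouped.size().to_numpy()})
    if len(out) < 2:
        raise InsufficientDataError("need samples in at least 2 distinct years")
    return out.sort_values("year").reset_index(drop=True)


def _design(years: np.ndarray) -> np.ndarray:
    return sm.add_constant(years - YEAR_ZERO)


def ols_trend(series: pd.DataFrame, variable: str = "value") -> TrendResult:
    """OLS of annual means on (year - 1985) with DW and BP diagnostics."""
    if len(series) < 3:
        raise InsufficientDataError("trend fit needs at least 3 years")
    y = series["value"].to_numpy(dtype=float)
    years = series["year"].to_numpy(dtype=float)
    fit = sm.OLS(y, _design(years)).fit()
    resid = fit.resid
    dw = durbin_watson(resid)
    bp_stat, bp_p = (breusch_pagan(resid, years - YEAR_ZERO)
                     if len(series) >= 4 else (np.nan, np.nan))
    return TrendResult(
        variable=variable,
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r2=float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0,
        p_value=float(fit.pvalues[1]), n_years=len(series),
        slope_se=float(fit.bse[1]),
        dw_stat=float(dw),
        dw_significant=(dw_decision(dw, len(series))
                        if len(series) >= 6 else False),
        bp_stat=bp_stat, bp_p=bp_p)


def durbin_watson(residuals) -> float:
    """DW = sum((e_t - e_{t-1})^2) / sum(e_t^2)."""
    resid = np.asarray(residuals, dtype=float)
    if len(resid) < 3:
        raise InsufficientDataError("Durbin-Watson needs at least 3 residuals")
    return float(_sm_dw(resid))


def dw_decision(dw_stat: float, n: int, k: int = 1,
                alpha: float = 0.05,
                method: Literal["normal", "bootstrap"] = "normal",
                residuals=None, n_boot: int = 2000,
                seed: int = 0) -> bool:
    """Two-sided significance decision for a Durbin-Watson statistic.

    Default is the large-sample normal approximation under the null
    (mean 2, variance 4/n). The bootstrap alternative resamples the supplied
    residuals with replacement, recomputes DW, and uses the empirical
    two-sided p-value; it conditions on the observed residual distribution
    rather than the design matrix.
    """
    if n < 6:
        raise InsufficientDataError("DW decision needs n >= 6")
    if method == "normal":
        z = (dw_stat - 2.0) / np.sqrt(4.0 / n)
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        return bool(p < alpha)
    if method == "bootstrap":
        if residuals is None:
            raise ValueError("bootstrap method requires residuals")
        resid = np.asarray(residuals, dtype=float)
        rng = np.random.default_rng(seed)
        null = np.array([float(_sm_dw(rng.choice(resid, size=len(resid))))
                         for _ in range(n_boot)])
        lo = np.mean(null <= dw_stat)
        hi = np.mean(null >= dw_stat)
        p = 2.0 * min(lo, hi)
        return bool(p < alpha)
    raise ValueError(f"unknown DW decision method {method!r}")


def cochrane_orcutt(series: pd.DataFrame, tol: float = 1e-6,
                    max_iter: int = 100) -> dict:
    """Iterative Cochrane-Orcutt AR(1) correction of the trend fit.

    Repeats: (1) estimate rho by lag-1 OLS of the residuals; (2)
    quasi-difference y*_t = y_t - rho y_{t-1}, x*_t = x_t - rho x_{t-1}
    (dropping the first observation, classic form); (3) refit. Stops when
    |delta rho| < ``tol`` or after ``max_iter`` iterations (flagged, last
    iterate returned). The corrected intercept is mapped back to the
    original scale by dividing by (1 - rho); the slope scale is unchanged.
    """
    if len(series) < 4:
        raise InsufficientDataError("Cochrane-Orcutt needs at least 4 years")
    y = series["value"].to_numpy(dtype=float)
    x = series["year"].to_numpy(dtype=float) - YEAR_ZERO
    X = sm.add_constant(x)
    params = sm.OLS(y, X).fit().params
    rho = 0.0
    converged = False
    for _ in range(max_iter):
        resid = y - X @ params
        denom = float(resid[:-1] @ resid[:-1])
        rho_new = float(resid[1:] @ resid[:-1]) / denom if denom > 0 else 0.0
        rho_new = float(np.clip(rho_new, -0.999, 0.999))
        y_star = y[1:] - rho_new * y[:-1]
        x_star = x[1:] - rho_new * x[:-1]
        fit_star = sm.OLS(y_star, sm.add_constant(x_star)).fit()
        # original-scale parameters feed the next residual pass
        params = np.array([fit_star.params[0] / (1.0 - rho_new),
                           fit_star.params[1]])
        if abs(rho_new - rho) < tol:
            rho = rho_new
            converged = True
            break
        rho = rho_new
    resid_star = fit_star.resid
    return {
        "rho_hat": rho,
        "slope": float(fit_star.params[1]),
        "slope_se": float(fit_star.bse[1]),
        "intercept": float(fit_star.params[0] / (1.0 - rho)),
        "p_value": float(fit_star.pvalues[1]),
        "r2": float(fit_star.rsquared),
        "dw_transformed": float(_sm_dw(resid_star)),
        "converged": converged,
    }


def breusch_pagan(residuals, regressor) -> tuple[float, float]:
    """Breusch-Pagan LM test of residual variance against one regressor.

    LM = n * R^2 from the auxiliary regression of squared residuals on the
    regressor; p from chi-square with 1 df. Constant residuals give LM = 0.
    """
    resid = np.asarray(residuals, dtype=float)
    x = np.asarray(regressor, dtype=float)
    if len(resid) < 4:
        raise InsufficientDataError("Breusch-Pagan needs at least 4 points")
    if np.allclose(resid, resid[0]):
        return 0.0, 1.0
    lm, lm_p, _, _ = het_breuschpagan(resid, sm.add_constant(x))
    return float(lm), float(lm_p)


def fit_trend(series: pd.DataFrame, variable: str = "value") -> TrendResult:
    """Full trend workflow: OLS, DW decision, Cochrane-Orcutt when needed.

    When the DW test flags significant autocorrelation (and >= 4 years are
    available) the Cochrane-Orcutt correction is run and its slope, intercept
    and p-value stored in the ``corrected_*`` fields; the uncorrected fit is
    always retained alongside.
    """
    res = ols_trend(series, variable=variable)
    if res.dw_significant and len(series) >= 4:
        co = cochrane_orcutt(series)
        res.corrected = True
        res.rho_hat = co["rho_hat"]
        res.corrected_slope = co["slope"]
        res.corrected_slope_se = co["slope_se"]
        res.corrected_intercept = co["intercept"]
        res.corrected_p = co["p_value"]
        res.co_converged = co["converged"]
    return res
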