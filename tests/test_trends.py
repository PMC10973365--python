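"""Trend fits, Durbin-Watson, Cochrane-Orcutt, Breusch-Pagan."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import plumemix as pm
from plumemix.errors import InsufficientDataError

from conftest import ar1


def series_from(values, start=1985):
    years = np.arange(start, start + len(values))
    return pd.DataFrame({"year": years, "value": np.asarray(values, float)})


# -------------------------------------------------------- annual means -----

def test_annual_means_arithmetic():
    df = pd.DataFrame({"date": ["2000-01-01", "2000-06-01", "2001-01-01"],
                       "dip_uM": [1.0, 3.0, 5.0]})
    out = pm.annual_means(df, "dip_uM")
    assert out["value"].tolist() == [2.0, 5.0]
    assert out["n"].tolist() == [2, 1]


def test_annual_means_requires_two_years():
    df = pd.DataFrame({"date": ["2000-01-01", "2000-06-01"],
                       "dip_uM": [1.0, 3.0]})
    with pytest.raises(InsufficientDataError):
        pm.annual_means(df, "dip_uM")


def test_annual_means_close_to_population_truth():
    rng = np.random.default_rng(12)
    frames = []
    for year, mu in [(2000, 2.0), (2001, 3.0), (2002, 4.0)]:
        frames.append(pd.DataFrame({
            "date": [f"{year}-06-01"] * 500,
            "dip_uM": rng.normal(mu, 0.5, 500)}))
    out = pm.annual_means(pd.concat(frames), "dip_uM")
    se = 0.5 / np.sqrt(500)
    for val, mu in zip(out["value"], [2.0, 3.0, 4.0]):
        assert abs(val - mu) < 3 * se


# ------------------------------------------------------------------ OLS ----

def test_ols_matches_closed_form_two_variable_least_squares():
    rng = np.random.default_rng(1)
    y = rng.normal(size=35)
    s = series_from(y)
    res = pm.ols_trend(s)
    x = s["year"].to_numpy(float) - 1985
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    intercept = y.mean() - slope * x.mean()
    assert res.slope == pytest.approx(slope, rel=1e-10)
    assert res.intercept == pytest.approx(intercept, rel=1e-10)


def test_perfect_line_and_constant_series(linear_series):
    res = pm.ols_trend(linear_series)
    assert res.slope == pytest.approx(0.1, rel=1e-12)
    assert res.intercept == pytest.approx(2.0, rel=1e-12)
    assert res.r2 == pytest.approx(1.0)
    flat = pm.ols_trend(series_from(np.full(10, 3.0)))
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    assert flat.r2 == pytest.approx(0.0, abs=1e-12)


def test_ols_slope_is_unbiased_over_replicates():
    rng = np.random.default_rng(2)
    slopes = []
    x = np.arange(35, dtype=float)
    for _ in range(500):
        slopes.append(pm.ols_trend(series_from(
            1.0 + 0.05 * x + rng.normal(0, 0.2, 35))).slope)
    assert np.mean(slopes) == pytest.approx(0.05, abs=0.005)


def test_intercept_is_at_year_1985():
    s = series_from([5.0, 5.1, 5.2, 5.3], start=1990)
    res = pm.ols_trend(s)
    # value at 1990 is 5.0, so the 1985 intercept extrapolates backwards
    assert res.intercept == pytest.approx(5.0 - 5 * res.slope, rel=1e-9)


# ---------------------------------------------------------- Durbin-Watson --

def test_durbin_watson_hand_evaluated():
    assert pm.durbin_watson([1.0, 2.0, 3.0]) == pytest.approx(2.0 / 14.0)


def test_durbin_watson_iid_near_two_and_alternating_near_four():
    rng = np.random.default_rng(3)
    assert 1.7 < pm.durbin_watson(rng.normal(size=1000)) < 2.3
    alt = np.tile([1.0, -1.0], 500)
    assert pm.durbin_watson(alt) == pytest.approx(4.0, abs=0.01)


def test_dw_decision_null_center_and_power():
    assert not pm.dw_decision(2.0, 35)
    rng = np.random.default_rng(4)
    hits = 0
    for _ in range(500):
        resid = ar1(35, 0.8, 1.0, rng)
        hits += pm.dw_decision(pm.durbin_watson(resid), 35)
    assert hits / 500 >= 0.90


def test_dw_bootstrap_decision_agrees_on_clear_cases():
    rng = np.random.default_rng(5)
    resid = ar1(60, 0.9, 1.0, rng)
    dw = pm.durbin_watson(resid)
    assert pm.dw_decision(dw, 60, method="bootstrap", residuals=resid, seed=0)


# -------------------------------------------------------- Cochrane-Orcutt --

def test_cochrane_orcutt_with_white_noise_matches_ols(linear_series):
    rng = np.random.default_rng(6)
    s = linear_series.copy()
    s["value"] += rng.normal(0, 0.05, len(s))
    co = pm.cochrane_orcutt(s)
    ols = pm.ols_trend(s)
    assert abs(co["rho_hat"]) < 0.35
    assert co["slope"] == pytest.approx(ols.slope, abs=0.01)
    assert co["converged"]


def test_cochrane_orcutt_recovers_rho():
    rng = np.random.default_rng(7)
    x = np.arange(200, dtype=float)
    s = series_from(2.0 + 0.03 * x + ar1(200, 0.6, 0.5, rng))
    co = pm.cochrane_orcutt(s)
    assert co["rho_hat"] == pytest.approx(0.6, abs=0.1)
    assert co["slope"] == pytest.approx(0.03, abs=0.01)


def test_cochrane_orcutt_moves_dw_toward_two():
    rng = np.random.default_rng(8)
    improved = 0
    for _ in range(100):
        x = np.arange(40, dtype=float)
        s = series_from(1.0 + 0.02 * x + ar1(40, 0.7, 0.3, rng))
        before = pm.ols_trend(s).dw_stat
        co = pm.cochrane_orcutt(s)
        improved += abs(co["dw_transformed"] - 2.0) < abs(before - 2.0)
    assert improved >= 95


def test_cochrane_orcutt_cross_checked_against_glsar():
    rng = np.random.default_rng(9)
    x = np.arange(50, dtype=float)
    y = 2.0 + 0.05 * x + ar1(50, 0.5, 0.4, rng)
    co = pm.cochrane_orcutt(series_from(y))
    glsar = sm.GLSAR(y, sm.add_constant(x), rho=1).iterative_fit(maxiter=100)
    assert co["slope"] == pytest.approx(float(glsar.params[1]), rel=0.05)
    assert co["rho_hat"] == pytest.approx(float(glsar.model.rho[0]), abs=0.05)


def test_forcing_rho_zero_reproduces_ols(linear_series):
    # quasi-differencing with rho = 0 is the identity transform
    s = linear_series
    y = s["value"].to_numpy()
    x = s["year"].to_numpy(float) - 1985
    fit = sm.OLS(y[1:] - 0.0 * y[:-1],
                 sm.add_constant(x[1:] - 0.0 * x[:-1])).fit()
    ols = pm.ols_trend(s)
    assert float(fit.params[1]) == pytest.approx(ols.slope, rel=1e-10)


# ---------------------------------------------------------- Breusch-Pagan --

def test_breusch_pagan_constant_residuals_give_zero():
    assert pm.breusch_pagan(np.ones(10), np.arange(10.0)) == (0.0, 1.0)


def test_breusch_pagan_detects_variance_growing_with_x():
    rng = np.random.default_rng(10)
    x = np.linspace(1, 10, 200)
    hits = 0
    for _ in range(50):
        resid = rng.normal(0, x)  # sd proportional to x
        _, p = pm.breusch_pagan(resid, x)
        hits += p < 0.05
    assert hits >= 40


# ------------------------------------------------------------ full fit -----

def test_full_pipeline_recovers_dip_trend_and_flags_flat_din():
    cfg = pm.SyntheticConfig(seed=30)
    s = pm.generate_surface_samples(cfg)
    retained, _ = pm.filter_samples(s)
    dip = pm.fit_trend(pm.annual_means(retained, "dip_uM"), "dip_uM")
    din = pm.fit_trend(pm.annual_means(retained, "din_uM"), "din_uM")
    assert dip.significant
    assert dip.slope > 0
    assert not din.significant
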