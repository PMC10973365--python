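"""Generator contracts: determinism, bounded draws, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import plumemix as pm
from plumemix.errors import ConfigurationError


def test_identical_seed_gives_byte_identical_tables(tmp_path):
    a = pm.generate_surface_samples(pm.SyntheticConfig(seed=5, samples_per_year=50))
    b = pm.generate_surface_samples(pm.SyntheticConfig(seed=5, samples_per_year=50))
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa, index=False)
    b.to_csv(pb, index=False)
    assert pa.read_bytes() == pb.read_bytes()
    r1 = pm.generate_river_series(pm.SyntheticConfig(seed=5))
    r2 = pm.generate_river_series(pm.SyntheticConfig(seed=5))
    pd.testing.assert_frame_equal(r1, r2)


def test_different_seeds_differ():
    a = pm.generate_surface_samples(pm.SyntheticConfig(seed=1, samples_per_year=20))
    b = pm.generate_surface_samples(pm.SyntheticConfig(seed=2, samples_per_year=20))
    assert not np.allclose(a["salinity"], b["salinity"])


@pytest.mark.parametrize("field, value", [
    ("p_excess", 1.5),
    ("rho", 1.0),
    ("ocean_salinity", -1.0),
    ("river_dip0", -0.1),
    ("samples_per_year", 0),
    ("bathy_resolution", 0.0),
    ("outlier_rate", -0.2),
])
def test_invalid_config_fields_raise_naming_the_field(field, value):
    with pytest.raises(ConfigurationError, match=field):
        pm.SyntheticConfig(**{field: value})


def test_don_exceeding_tdn_is_a_configuration_error():
    base = pm.SyntheticConfig().river_base
    base["don_conc"] = base["tdn_conc"] + 1.0
    with pytest.raises(ConfigurationError, match="don_conc"):
        pm.SyntheticConfig(river_base=base)


def test_p_excess_zero_puts_no_dip_above_the_line():
    cfg = pm.SyntheticConfig(seed=3, p_excess=0.0, outlier_rate=0.0,
                             samples_per_year=100)
    s = pm.generate_surface_samples(cfg)
    assert not s["truth_above_dip"].any()
    # verify against the year-specific lines, not just the bookkeeping flag
    assert (s["dip_uM"] <= s["truth_dip_line_uM"]).all()


def test_dip_draws_bounded_by_tdp_line_before_outliers():
    cfg = pm.SyntheticConfig(seed=4, p_excess=1.0, outlier_rate=0.0,
                             samples_per_year=200)
    s = pm.generate_surface_samples(cfg)
    assert (s["dip_uM"] <= s["truth_tdp_line_uM"] + 1e-9).all()


def test_year_specific_line_truth_matches_expected_endmembers():
    cfg = pm.SyntheticConfig(seed=12, annual_sd=0.0, samples_per_year=50)
    s = pm.generate_surface_samples(cfg)
    expected = pm.expected_annual_dip_endmembers(cfg).set_index("year")
    years = pd.to_datetime(s["date"]).dt.year
    dil = 1.0 - s["salinity"] / cfg.ocean_salinity
    line = expected.loc[years, "dip_uM"].to_numpy() * dil
    np.testing.assert_allclose(s["truth_dip_line_uM"], line, rtol=1e-12)


def test_fraction_above_dip_line_matches_p_excess(default_samples,
                                                 default_config):
    frac = default_samples["truth_above_dip"].mean()
    assert frac == pytest.approx(default_config.p_excess, abs=0.05)


def test_annual_mean_dip_recovers_configured_trend():
    cfg = pm.SyntheticConfig(seed=7, rho=0.0, annual_sd=0.01,
                             outlier_rate=0.0, samples_per_year=400)
    s = pm.generate_surface_samples(cfg)
    series = pm.annual_means(s, "dip_uM")
    res = pm.ols_trend(series)
    half = 1.96 * res.slope_se
    assert res.slope - half <= cfg.dip_trend <= res.slope + half


def test_ar1_lag1_autocorrelation_recovery():
    rng = np.random.default_rng(0)
    x = pm.ar1_series(500, rho=0.6, sd=1.0, rng=rng)
    r = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert r == pytest.approx(0.6, abs=0.1)
    assert np.std(x) == pytest.approx(1.0, abs=0.15)


def test_outlier_injection_exceeds_qc_thresholds():
    cfg = pm.SyntheticConfig(seed=9, outlier_rate=0.05, samples_per_year=200)
    s = pm.generate_surface_samples(cfg)
    out = s[s["truth_outlier"]]
    assert len(out) > 0
    assert ((out["din_uM"] > cfg.din_max) | (out["dip_uM"] > cfg.dip_max)).all()
    clean = s[~s["truth_outlier"]]
    assert (clean["din_uM"] <= cfg.din_max).all()
    assert (clean["dip_uM"] <= cfg.dip_max).all()


def test_summer_sampling_bias(default_samples, default_config):
    months = pd.to_datetime(default_samples["date"]).dt.month
    summer = months.isin([6, 7, 8]).mean()
    assert summer == pytest.approx(default_config.summer_fraction, abs=0.03)


# ---------------------------------------------------------------- river ----

def test_river_zero_trend_zero_noise_is_constant():
    cfg = pm.SyntheticConfig(seed=1, river_trend_pct={}, river_noise_cv=0.0)
    r = pm.generate_river_series(cfg)
    for col in r.columns.drop("year"):
        assert r[col].nunique() == 1


def test_river_configured_load_trend_recovered():
    cfg = pm.SyntheticConfig(seed=2, river_trend_pct={"dip_conc": 1.0},
                             river_noise_cv=0.03, rho=0.0)
    r = pm.generate_river_series(cfg)
    res = pm.ols_trend(r.rename(columns={"dip_load": "value"})[["year", "value"]])
    assert res.slope > 0
    assert res.p_value < 0.05


def test_river_organic_never_exceeds_totals():
    r = pm.generate_river_series(pm.SyntheticConfig(seed=3, river_noise_cv=0.4))
    assert (r["don_conc"] <= r["tdn_conc"]).all()
    assert (r["dop_conc"] <= r["tdp_conc"]).all()
    assert (r["don_load"] <= r["tdn_load"]).all()


# ----------------------------------------------------------- bathymetry ----

def test_bathymetry_deepens_offshore_and_covers_samples(default_config,
                                                        default_samples):
    grid = pm.generate_bathymetry(default_config)
    assert (grid > 0).all()
    depth = grid.to_numpy()
    # lat decreasing == moving offshore: depth increases southward everywhere
    assert (np.diff(depth, axis=0) <= 0).all()
    # every generated coordinate has a containing cell
    depths = pm.lookup_bottom_depth(default_samples["lat"].to_numpy(),
                                    default_samples["lon"].to_numpy(), grid)
    assert np.isfinite(depths).all()


def test_bathymetry_lookup_matches_direct_indexing(default_config):
    grid = pm.generate_bathymetry(default_config)
    lat = float(grid["lat"][5])
    lon = float(grid["lon"][7])
    assert pm.lookup_bottom_depth(lat, lon, grid) == pytest.approx(
        float(grid[5, 7]))


# -------------------------------------------------------------- hypoxia ----

def test_hypoxia_constant_when_decoupled_and_noiseless():
    cfg = pm.SyntheticConfig(seed=1, hypoxia_slope_km2_per_kg=0.0,
                             hypoxia_noise_sd_km2=0.0, river_noise_cv=0.0,
                             river_trend_pct={})
    r = pm.generate_river_series(cfg)
    h = pm.generate_hypoxic_series(cfg, r)
    assert h["area_km2"].nunique() == 1


def test_hypoxia_tracks_din_load_at_low_noise():
    cfg = pm.SyntheticConfig(seed=6, hypoxia_noise_sd_km2=100.0)
    r = pm.generate_river_series(cfg)
    h = pm.generate_hypoxic_series(cfg, r)
    assert np.corrcoef(h["area_km2"], r["din_load"])[0, 1] > 0.8


def test_hypoxia_truncated_at_zero():
    cfg = pm.SyntheticConfig(seed=6, hypoxia_intercept_km2=0.0,
                             hypoxia_slope_km2_per_kg=0.0,
                             hypoxia_noise_sd_km2=5000.0)
    r = pm.generate_river_series(cfg)
    h = pm.generate_hypoxic_series(cfg, r)
    assert (h["area_km2"] >= 0).all()
    assert (h["area_km2"] == 0).any()
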