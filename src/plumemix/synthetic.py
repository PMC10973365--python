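"""Seeded synthetic bottle-sample, river, bathymetry and hypoxia generators.

The generators emulate the statistical structure of a compiled surface-nutrient
data set spanning a river-to-ocean salinity gradient: dissolved inorganic
nitrogen (DIN) declining faster with salinity than dissolved inorganic
phosphorus (DIP), a configurable fraction of DIP samples falling above the
conservative DIP mixing line (bounded above by the TDP line), a linear trend in
the annual DIP level with AR(1) year-to-year deviations, detection-limit
censoring, and rare extreme outliers that downstream quality control is
expected to remove.

All randomness flows from a single integer seed through named substreams
(:func:`substream`), so each artifact can be regenerated independently and
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "substream",
    "ar1_series",
    "generate_surface_samples",
    "expected_annual_dip_endmembers",
    "generate_river_series",
    "generate_bathymetry",
    "generate_hypoxic_series",
]

#: fixed substream indices so artifacts are independently regenerable
_STREAMS = {"surface": 0, "river": 1, "bathymetry": 2, "hypoxia": 3}

SAMPLE_COLUMNS = [
    "date", "lat", "lon", "depth_m", "salinity", "din_uM", "dip_uM",
    "truth_above_dip", "truth_outlier", "truth_dip_line_uM",
    "truth_tdp_line_uM",
]

#: salinity mixture: plume-weighted low component and offshore-weighted high
#: component, scaled to [0, ocean_salinity]
W_OFFSHORE = 0.55
BETA_PLUME = (1.2, 3.5)
BETA_OFFSHORE = (5.0, 1.6)


def _mixture_mean_dilution() -> float:
    """E[1 - s/s_max] under the salinity mixture (Beta means are analytic)."""
    mean_frac = (W_OFFSHORE * BETA_OFFSHORE[0] / sum(BETA_OFFSHORE)
                 + (1.0 - W_OFFSHORE) * BETA_PLUME[0] / sum(BETA_PLUME))
    return 1.0 - mean_frac


def _expected_base_dip(config: "SyntheticConfig") -> float:
    """Expected per-sample DIP (µM) at the baseline annual level.

    Below-line draws average half the DIP line; excess draws average the
    midpoint of the DIP and TDP lines.
    """
    p = config.p_excess
    per_unit = ((1.0 - p) * config.river_dip0 / 2.0
                + p * (config.river_dip0 + config.river_tdp0) / 2.0)
    return _mixture_mean_dilution() * per_unit


def expected_annual_dip_endmembers(config: "SyntheticConfig") -> pd.DataFrame:
    """Deterministic per-year DIP/TDP river endmembers implied by the trend.

    The annual level (µM added to the mean) maps to a multiplicative factor
    on the whole DIP field; the AR(1) deviations add mean-zero noise around
    these expectations.
    """
    a_base = _expected_base_dip(config)
    t = np.arange(config.n_years, dtype=float)
    f = 1.0 + config.dip_trend * t / a_base
    return pd.DataFrame({
        "year": np.arange(config.years[0], config.years[1] + 1),
        "dip_uM": config.river_dip0 * f,
        "tdp_uM": config.river_tdp0 * f,
    })


def _default_river_base() -> dict:
    # mg/L concentrations and m^3/yr discharge; TDN = DIN + DON and
    # TDP = DIP + DOP hold at the base values (0.068 mg/L P == 2.2 uM,
    # 0.102 mg/L P == 3.3 uM, matching the surface endmembers)
    return {
        "discharge": 6.8e11,
        "din_conc": 1.44,
        "don_conc": 0.56,
        "tdn_conc": 2.00,
        "dip_conc": 0.068,
        "dop_conc": 0.034,
        "tdp_conc": 0.102,
        "sediment_conc": 150.0,
    }


def _default_river_trends() -> dict:
    # percent per year, applied multiplicatively to the base value;
    # load trends follow as concentration x discharge
    return {"dip_conc": 1.0, "dop_conc": 1.0}


@dataclass
class SyntheticConfig:
    """Parameters controlling every synthetic artifact.

    Concentrations are in µM unless stated otherwise; salinity in ppt.
    ``dip_trend`` is the additive change in the annual DIP level (µM per
    year); ``rho`` and ``annual_sd`` define the stationary AR(1) process of
    annual-level deviations; ``noise_cv`` is the coefficient of variation of
    the multiplicative lognormal noise on per-sample DIN.
    """

    years: tuple[int, int] = (1985, 2019)
    samples_per_year: int = 300
    river_din0: float = 103.0
    river_dip0: float = 2.2
    river_tdp0: float = 3.3
    ocean_salinity: float = 37.0
    din_loss_rate: float = 0.12
    p_excess: float = 0.5
    dip_trend: float = 0.02
    rho: float = 0.15
    noise_cv: float = 0.3
    annual_sd: float = 0.2
    annual_cv_din: float = 0.25
    outlier_rate: float = 0.005
    summer_fraction: float = 0.6
    dl_din: float = 0.05
    dl_dip: float = 0.03
    din_max: float = 110.0
    dip_max: float = 8.0
    bbox: tuple[float, float, float, float] = (-98.0, -79.0, 22.5, 31.0)
    bathy_resolution: float = 0.25
    bathy_max_depth: float = 3500.0
    river_base: dict = field(default_factory=_default_river_base)
    river_trend_pct: dict = field(default_factory=_default_river_trends)
    river_noise_cv: float = 0.05
    hypoxia_intercept_km2: float = 2000.0
    hypoxia_slope_km2_per_kg: float = 1.0e-5
    hypoxia_noise_sd_km2: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.p_excess <= 1.0):
            raise ConfigurationError("p_excess must lie in [0, 1]")
        if not abs(self.rho) < 1.0:
            raise ConfigurationError("rho must satisfy |rho| < 1")
        if self.ocean_salinity <= 0:
            raise ConfigurationError("ocean_salinity must be positive")
        for name in ("river_din0", "river_dip0", "river_tdp0"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.river_tdp0 < self.river_dip0:
            raise ConfigurationError("river_tdp0 must be >= river_dip0")
        if self.river_tdp0 >= self.dip_max:
            raise ConfigurationError(
                "river_tdp0 must stay below dip_max so only injected outliers "
                "violate the nutrient thresholds")
        if self.years[1] < self.years[0]:
            raise ConfigurationError("years range is reversed")
        if self.samples_per_year < 1:
            raise ConfigurationError("samples_per_year must be >= 1")
        if not (0.0 <= self.summer_fraction <= 1.0):
            raise ConfigurationError("summer_fraction must lie in [0, 1]")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ConfigurationError("outlier_rate must lie in [0, 1]")
        if self.bathy_resolution <= 0:
            raise ConfigurationError("bathy_resolution must be positive")
        rb = self.river_base
        if rb.get("don_conc", 0.0) > rb.get("tdn_conc", np.inf):
            raise ConfigurationError("river_base: don_conc must be <= tdn_conc")
        if rb.get("dop_conc", 0.0) > rb.get("tdp_conc", np.inf):
            raise ConfigurationError("river_base: dop_conc must be <= tdp_conc")
        for key, val in rb.items():
            if val < 0:
                raise ConfigurationError(f"river_base: {key} must be non-negative")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("years", "bbox"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named artifact, derived from one seed."""
    try:
        idx = _STREAMS[name]
    except KeyError:
        raise ConfigurationError(f"unknown substream {name!r}") from None
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


def ar1_series(n: int, rho: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) deviations with lag-1 coefficient ``rho``.

    Innovations are scaled so the marginal standard deviation equals ``sd``
    at every index (the first draw comes from the stationary distribution).
    """
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + eps[t - 1]
    return out


def _lognormal_factor(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _draw_dates(year: int, n: int, summer_fraction: float,
                rng: np.random.Generator) -> pd.Series:
    summer = rng.random(n) < summer_fraction
    months = np.where(summer, rng.integers(6, 9, size=n),
                      rng.choice([1, 2, 3, 4, 5, 9, 10, 11, 12], size=n))
    days = rng.integers(1, 29, size=n)
    return pd.to_datetime(
        {"year": np.full(n, year), "month": months, "day": days})


def generate_surface_samples(config: SyntheticConfig) -> pd.DataFrame:
    """Draw ``samples_per_year`` surface bottle samples for each year.

    Per sample: salinity comes from a two-component Beta mixture (a
    plume-weighted low-salinity component and an offshore-weighted
    high-salinity component) scaled to [0, ocean_salinity]; DIN follows the
    river-to-ocean dilution line multiplied by exp(-din_loss_rate * s) and
    unit-mean lognormal noise; DIP is drawn uniformly below the year's DIP
    mixing line with probability 1 - p_excess and uniformly between the DIP
    and TDP lines with probability p_excess. The annual DIP level (trend plus
    AR(1) deviation, in µM on the annual mean) is applied as a multiplicative
    factor scaling the sample draws and the year's lines together, normalized
    by the analytic expected baseline, so annual-mean DIP has expected slope
    ``dip_trend`` while the bounded-draw guarantees hold relative to the
    year-specific lines and the field stays non-negative.

    Returns a DataFrame with the columns in :data:`SAMPLE_COLUMNS`; the
    ``truth_`` columns are generator bookkeeping for downstream tests (which
    DIP draws lie strictly above the year's DIP line, which records carry an
    injected outlier, and the year-specific line predictions at each sample's
    salinity).
    """
    config.validate()
    rng = substream(config.seed, "surface")
    y0, y1 = config.years
    n_years = config.n_years
    n = config.samples_per_year
    smax = config.ocean_salinity
    lon_min, lon_max, lat_min, lat_max = config.bbox

    dip_dev = ar1_series(n_years, config.rho, config.annual_sd, rng)
    # DIN annual level varies multiplicatively (keeps the field positive and
    # proportional to the dilution line at every salinity)
    din_level = np.maximum(
        1.0 + ar1_series(n_years, config.rho, config.annual_cv_din, rng), 0.05)

    frames = []
    a_base = _expected_base_dip(config)
    for t in range(n_years):
        year = y0 + t
        # salinity: plume (low) vs offshore (high) mixture
        offshore = rng.random(n) < W_OFFSHORE
        s = np.where(offshore,
                     rng.beta(*BETA_OFFSHORE, size=n),
                     rng.beta(*BETA_PLUME, size=n)) * smax
        lon = rng.uniform(lon_min + 0.25, lon_max - 0.25, size=n)
        off_frac = np.clip(s / smax + rng.normal(0.0, 0.15, size=n), 0.0, 1.0)
        lat = (lat_max - 0.3) - off_frac * (lat_max - lat_min - 0.6)
        depth = rng.uniform(0.0, 5.0, size=n)
        dates = _draw_dates(year, n, config.summer_fraction, rng)

        dilution = 1.0 - s / smax
        din = (config.river_din0 * din_level[t] * dilution
               * np.exp(-config.din_loss_rate * s)
               * _lognormal_factor(config.noise_cv, n, rng))
        din = np.minimum(din, config.din_max)
        din[din < config.dl_din] = 0.0

        # the additive annual level (µM on the annual mean) becomes a
        # multiplicative factor on the whole DIP field, scaling sample draws
        # and the year's mixing lines together
        level_factor = max(1.0 + (config.dip_trend * t + dip_dev[t]) / a_base,
                           0.05)
        dip_line = config.river_dip0 * dilution * level_factor
        tdp_line = config.river_tdp0 * dilution * level_factor
        excess = rng.random(n) < config.p_excess
        u = rng.random(n)
        dip = np.where(excess,
                       dip_line + u * (tdp_line - dip_line),
                       u * dip_line)
        dip[dip < config.dl_dip] = 0.0
        above = dip > dip_line

        outlier = rng.random(n) < config.outlier_rate
        if outlier.any():
            k = int(outlier.sum())
            which_din = rng.random(k) < 0.5
            big_din = rng.uniform(config.din_max + 1.0, 300.0, size=k)
            big_dip = rng.uniform(config.dip_max + 0.5, 20.0, size=k)
            din[outlier] = np.where(which_din, big_din, din[outlier])
            dip[outlier] = np.where(~which_din, big_dip, dip[outlier])
            above[outlier] = False

        frames.append(pd.DataFrame({
            "date": dates, "lat": lat, "lon": lon, "depth_m": depth,
            "salinity": s, "din_uM": din, "dip_uM": dip,
            "truth_above_dip": above, "truth_outlier": outlier,
            "truth_dip_line_uM": dip_line, "truth_tdp_line_uM": tdp_line,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_river_series(config: SyntheticConfig) -> pd.DataFrame:
    """Annual river endmember records with configurable trends + AR(1) noise.

    Each base variable follows ``base * (1 + trend_pct/100 * t) * (1 + dev_t)``
    with an independent AR(1) deviation stream per variable. TDN and TDP are
    computed as DIN + DON and DIP + DOP so the organic <= total invariants
    hold by construction. Loads (kg/yr) are concentration (mg/L == g/m^3)
    times discharge (m^3/yr) / 1000.
    """
    config.validate()
    rng = substream(config.seed, "river")
    y0, y1 = config.years
    n = config.n_years
    t = np.arange(n, dtype=float)
    base = config.river_base
    trends = config.river_trend_pct

    values: dict[str, np.ndarray] = {}
    for var in ("discharge", "din_conc", "don_conc", "dip_conc", "dop_conc",
                "sediment_conc"):
        dev = ar1_series(n, config.rho, config.river_noise_cv, rng)
        trend = trends.get(var, 0.0) / 100.0
        values[var] = np.maximum(base[var] * (1.0 + trend * t) * (1.0 + dev), 0.0)
    values["tdn_conc"] = values["din_conc"] + values["don_conc"]
    values["tdp_conc"] = values["dip_conc"] + values["dop_conc"]

    out = pd.DataFrame({"year": np.arange(y0, y1 + 1)})
    out["discharge"] = values["discharge"]
    for nutrient in ("din", "dip", "tdn", "tdp", "don", "dop"):
        out[f"{nutrient}_conc"] = values[f"{nutrient}_conc"]
        out[f"{nutrient}_load"] = values[f"{nutrient}_conc"] * values["discharge"] / 1000.0
    out["sediment_conc"] = values["sediment_conc"]
    return out


def generate_bathymetry(config: SyntheticConfig) -> xr.DataArray:
    """Regular lat/lon grid of positive-down bottom depth (m).

    Depth deepens monotonically southward (offshore) at every longitude,
    from a few metres at the coastal edge to ``bathy_max_depth`` at the
    southern edge, with a gentle longitudinal modulation so neighbouring
    columns differ.
    """
    config.validate()
    lon_min, lon_max, lat_min, lat_max = config.bbox
    res = config.bathy_resolution
    lats = np.arange(lat_min + res / 2.0, lat_max, res)
    lons = np.arange(lon_min + res / 2.0, lon_max, res)
    frac = (lat_max - lats) / (lat_max - lat_min)
    profile = 5.0 + (config.bathy_max_depth - 5.0) * frac ** 3
    ripple = 1.0 + 0.08 * np.sin((lons - lon_min) / 3.0)
    depth = np.outer(profile, ripple)
    return xr.DataArray(depth, coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"), name="depth_m",
                        attrs={"units": "m", "positive": "down"})


def generate_hypoxic_series(config: SyntheticConfig,
                            river: pd.DataFrame) -> pd.DataFrame:
    """Annual hypoxic bottom-water area coupled linearly to the DIN load.

    area_km2 = intercept + slope * din_load + Normal(0, noise_sd),
    truncated at zero.
    """
    config.validate()
    if river.empty:
        raise ConfigurationError("river series must be nonempty")
    rng = substream(config.seed, "hypoxia")
    noise = (rng.normal(0.0, config.hypoxia_noise_sd_km2, size=len(river))
             if config.hypoxia_noise_sd_km2 > 0 else np.zeros(len(river)))
    area = (config.hypoxia_intercept_km2
            + config.hypoxia_slope_km2_per_kg * river["din_load"].to_numpy()
            + noise)
    return pd.DataFrame({"year": river["year"].to_numpy(),
                         "area_km2": np.maximum(area, 0.0)})
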