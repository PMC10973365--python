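"""Bottom-depth attachment and hypoxic / shelf / offshore classification.

The hypoxic region is a fixed shallow box on the shelf (lon -95..-88,
lat 27..29, bottom depth < 60 m); the shelf is everything shallower than
200 m and offshore everything deeper. The hypoxic subset is by definition a
subset of the shelf, so membership is returned both as boolean flags and as
a single most-specific primary label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError, DataError, LookupError_

__all__ = ["RegionConfig", "lookup_bottom_depth", "attach_bottom_depth",
           "classify_region", "load_bathymetry_grid"]

REGIONS = ("hypoxic", "shelf", "offshore")


@dataclass
class RegionConfig:
    hypoxic_bbox: tuple[float, float, float, float] = (-95.0, -88.0, 27.0, 29.0)
    hypoxic_depth_max: float = 60.0
    shelf_depth_max: float = 200.0

    def __post_init__(self) -> None:
        if self.hypoxic_depth_max >= self.shelf_depth_max:
            raise ConfigurationError(
                "hypoxic_depth_max must be less than shelf_depth_max")

    def to_dict(self) -> dict:
        return asdict(self)


def load_bathymetry_grid(path: str) -> xr.DataArray:
    """Read a bathymetry grid from long-format CSV (lat, lon, depth_m) or
    NetCDF; negative (positive-up) ocean depths are sign-normalized to
    positive-down on load."""
    if str(path).endswith((".nc", ".cdf", ".netcdf")):
        ds = xr.open_dataset(path)
        name = "depth_m" if "depth_m" in ds else "depth"
        grid = ds[name].transpose("lat", "lon").load()
    else:
        df = pd.read_csv(path)
        grid = (df.set_index(["lat", "lon"])["depth_m"]
                .to_xarray().transpose("lat", "lon"))
    if float(grid.median()) < 0:
        grid = -grid
    grid.name = "depth_m"
    return grid


def _nearest_index(coords: np.ndarray, values: np.ndarray,
                   res: float) -> np.ndarray:
    """Nearest-cell-center indices; -1 where outside the grid extent."""
    idx = np.clip(np.searchsorted(coords, values), 1, len(coords) - 1)
    left = values - coords[idx - 1] <= coords[idx] - values
    idx = np.where(left, idx - 1, idx)
    inside = ((values >= coords[0] - res / 2.0)
              & (values <= coords[-1] + res / 2.0))
    return np.where(inside, idx, -1)


def lookup_bottom_depth(lat, lon, grid: xr.DataArray):
    """Depth (m) of the grid cell whose center is nearest each coordinate.

    Raises a lookup error carrying the first offending coordinate if any
    point falls outside the grid extent (cell edges, i.e. centers +- half a
    cell).
    """
    lat_arr = np.atleast_1d(np.asarray(lat, dtype=float))
    lon_arr = np.atleast_1d(np.asarray(lon, dtype=float))
    lats = grid["lat"].to_numpy()
    lons = grid["lon"].to_numpy()
    res_lat = np.median(np.diff(lats)) if len(lats) > 1 else np.inf
    res_lon = np.median(np.diff(lons)) if len(lons) > 1 else np.inf
    i = _nearest_index(lats, lat_arr, res_lat)
    j = _nearest_index(lons, lon_arr, res_lon)
    bad = (i < 0) | (j < 0)
    if bad.any():
        k = int(np.argmax(bad))
        raise LookupError_(
            f"coordinate (lat={lat_arr[k]:.4f}, lon={lon_arr[k]:.4f}) "
            "outside bathymetry grid extent")
    depth = grid.to_numpy()[i, j]
    return float(depth[0]) if np.isscalar(lat) or np.ndim(lat) == 0 else depth


def attach_bottom_depth(samples: pd.DataFrame,
                        grid: xr.DataArray) -> pd.DataFrame:
    """Append a ``bottom_depth_m`` column from the nearest grid cell."""
    out = samples.copy()
    out["bottom_depth_m"] = lookup_bottom_depth(
        out["lat"].to_numpy(), out["lon"].to_numpy(), grid)
    return out


def classify_region(samples: pd.DataFrame,
                    rc: RegionConfig | None = None) -> pd.DataFrame:
    """Classify each sample into hypoxic / shelf / offshore subsets.

    Appends boolean membership flags (``is_hypoxic``, ``is_shelf``,
    ``is_offshore``) and a primary ``region`` label (the most specific
    membership). Hypoxic membership requires both the hypoxic bounding box
    and bottom depth < 60 m, and implies shelf membership. A bottom depth of
    exactly 200 m satisfies neither "< 200" nor "> 200"; such samples are
    assigned to the shelf and a boundary warning is emitted.
    """
    rc = rc or RegionConfig()
    if "bottom_depth_m" not in samples:
        raise ConfigurationError(
            "bottom_depth_m missing; call attach_bottom_depth first")
    depth = samples["bottom_depth_m"].to_numpy(dtype=float)
    if (depth < 0).any():
        raise DataError("negative bottom depth encountered")
    lon_min, lon_max, lat_min, lat_max = rc.hypoxic_bbox
    in_box = (samples["lon"].between(lon_min, lon_max)
              & samples["lat"].between(lat_min, lat_max)).to_numpy()

    at_boundary = depth == rc.shelf_depth_max
    if at_boundary.any():
        warnings.warn(
            f"{int(at_boundary.sum())} sample(s) at exactly "
            f"{rc.shelf_depth_max:g} m bottom depth assigned to shelf",
            stacklevel=2)
    is_shelf = depth <= rc.shelf_depth_max  # boundary -> shelf
    is_offshore = depth > rc.shelf_depth_max
    is_hypoxic = in_box & (depth < rc.hypoxic_depth_max) & is_shelf

    out = samples.copy()
    out["is_hypoxic"] = is_hypoxic
    out["is_shelf"] = is_shelf
    out["is_offshore"] = is_offshore
    out["region"] = np.where(is_hypoxic, "hypoxic",
                             np.where(is_shelf, "shelf", "offshore"))
    return out
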