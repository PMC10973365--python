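"""CSV readers/writers with per-record rejection logging."""

from __future__ import annotations

import logging

import pandas as pd
import xarray as xr

log = logging.getLogger("plumemix")

SAMPLE_NUMERIC = ("lat", "lon", "depth_m", "salinity", "din_uM", "dip_uM")


def read_samples_csv(path: str) -> pd.DataFrame:
    """Read a surface-sample table, rejecting unparseable records.

    Rows whose date or coordinates cannot be parsed are dropped and logged
    individually with their 1-based data line number; missing salinity or
    nutrient values are kept as NaN for the QC filter to attribute.
    """
    df = pd.read_csv(path)
    for col in SAMPLE_NUMERIC:
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    dates = pd.to_datetime(df["date"], errors="coerce")
    bad = dates.isna() | df["lat"].isna() | df["lon"].isna() | df["depth_m"].isna()
    for idx in df.index[bad]:
        log.warning("rejecting unparseable record at line %d of %s",
                    idx + 2, path)
    df = df.loc[~bad].reset_index(drop=True)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def grid_to_csv(grid: xr.DataArray, path: str) -> None:
    """Write a bathymetry grid as long-format lat, lon, depth_m."""
    grid.to_dataframe().reset_index()[["lat", "lon", "depth_m"]].to_csv(
        path, index=False)
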