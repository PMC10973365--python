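"""Pearson correlations between river, regional-mean, and hypoxia series.

All pairings are contemporaneous annual inner joins; years missing from
either series are dropped pairwise per comparison. Significance is judged at
alpha = 0.05 per test; a Benjamini-Hochberg adjusted column is additionally
emitted for users who want family-wise control (it plays no role in the
per-test significance flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InsufficientDataError

__all__ = ["CorrelationResult", "align_years", "pearson",
           "correlation_matrix"]

RIVER_VARS = ("discharge", "din_conc", "dip_conc", "tdn_conc", "tdp_conc",
              "don_conc", "dop_conc", "din_load", "dip_load", "tdn_load",
              "tdp_load", "don_load", "dop_load", "sediment_conc")
NGOM_VARS = ("din_uM", "dip_uM", "din_dip")
REGION_SUBSETS = ("all", "hypoxic", "shelf", "offshore")


@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    region: str
    r: float
    p_value: float
    n_years: int
    significant: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def align_years(series_a: pd.DataFrame,
                series_b: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two (year, value) tables on year, order preserved."""
    if series_a.empty or series_b.empty:
        raise InsufficientDataError("both series must be nonempty")
    a = series_a.rename(columns={series_a.columns[-1]: "x"})[["year", "x"]]
    b = series_b.rename(columns={series_b.columns[-1]: "y"})[["year", "y"]]
    return a.merge(b, on="year", how="inner").sort_values("year")


def pearson(pairs: pd.DataFrame, variable_x: str = "x",
            variable_y: str = "y", region: str = "all") -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p-value."""
    if len(pairs) < 3:
        raise InsufficientDataError("Pearson correlation needs >= 3 pairs")
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateInputError("zero variance in a correlation input")
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationResult(variable_x=variable_x, variable_y=variable_y,
                             region=region, r=float(r), p_value=float(p),
                             n_years=len(pairs), significant=bool(p < 0.05))


def _safe_pearson(pairs, vx, vy, region) -> CorrelationResult:
    try:
        return pearson(pairs, vx, vy, region)
    except (InsufficientDataError, DegenerateInputError):
        return CorrelationResult(variable_x=vx, variable_y=vy, region=region,
                                 r=np.nan, p_value=np.nan,
                                 n_years=len(pairs), significant=False,
                                 degenerate=True)


def correlation_matrix(river: pd.DataFrame,
                       regional_means: pd.DataFrame,
                       hypoxia: pd.DataFrame | None = None,
                       river_vars=RIVER_VARS,
                       ngom_vars=NGOM_VARS) -> pd.DataFrame:
    """The full tidy correlation grid.

    ``regional_means`` is long-format (region, variable, year, value) annual
    means of the surface nutrient data, one row set per regional subset.
    Emits every river variable x every regional nutrient variable x every
    region, plus hypoxic-area rows against river loads and regional
    nutrients. A ``p_bh`` Benjamini-Hochberg column is appended across all
    non-degenerate rows.
    """
    rows: list[CorrelationResult] = []
    for region in regional_means["region"].unique():
        sub = regional_means[regional_means["region"] == region]
        for ngom_var in ngom_vars:
            ser = sub[sub["variable"] == ngom_var][["year", "value"]]
            if ser.empty:
                continue
            for rv in river_vars:
                if rv not in river.columns:
                    continue
                pairs = align_years(river[["year", rv]], ser)
                rows.append(_safe_pearson(pairs, rv, ngom_var, region))
            if hypoxia is not None:
                pairs = align_years(hypoxia[["year", "area_km2"]], ser)
                rows.append(_safe_pearson(pairs, "area_km2", ngom_var, region))
    if hypoxia is not None:
        for rv in river_vars:
            if rv not in river.columns:
                continue
            pairs = align_years(river[["year", rv]],
                                hypoxia[["year", "area_km2"]])
            rows.append(_safe_pearson(pairs, rv, "area_km2", "hypoxia_area"))

    out = pd.DataFrame([r.to_dict() for r in rows])
    out["p_bh"] = np.nan
    ok = ~out["degenerate"]
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p_value"],
                                            method="fdr_bh")[1]
    return out
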