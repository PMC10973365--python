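"""Two-endmember conservative mixing lines and residual analysis.

A conservative mixing line connects the river endmember concentration at
salinity 0 to the ocean endmember at salinity ``s_max`` (37 ppt). Samples on
the line are explained by dilution alone; positive residuals indicate a
nutrient source beyond the river endmember, negative residuals net loss
(e.g. phytoplankton uptake). DIP residuals are further classified against
the nested DIP and TDP lines — a DIP value above the DIP line but below the
TDP line is consistent with in-situ conversion of riverine organic P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, InsufficientDataError, DegenerateInputError

__all__ = [
    "MixingLine", "build_mixing_line", "residuals", "classify_dip_residual",
    "fraction_above", "ln_salinity_regression", "annual_mixing_lines",
    "LnRegressionResult",
]

DIP_CLASSES = ("above_both", "above_dip_below_tdp", "below_dip")


@dataclass(frozen=True)
class MixingLine:
    """Linear conservative mixing function in concentration-salinity space."""

    river_conc: float
    ocean_conc: float
    s_max: float = 37.0

    def __post_init__(self) -> None:
        if self.s_max <= 0:
            raise ConfigurationError("s_max must be positive")
        if self.river_conc < 0 or self.ocean_conc < 0:
            raise ConfigurationError("endmember concentrations must be >= 0")

    @property
    def slope(self) -> float:
        return (self.ocean_conc - self.river_conc) / self.s_max

    @property
    def intercept(self) -> float:
        return self.river_conc

    def predict(self, salinity):
        """Expected concentration from dilution alone; exact at both
        endmembers."""
        s = np.asarray(salinity, dtype=float)
        out = self.river_conc + self.slope * s
        # pin the ocean endmember against floating-point drift
        out = np.where(s == self.s_max, self.ocean_conc, out)
        return float(out) if np.ndim(salinity) == 0 else out


def build_mixing_line(river_conc: float, ocean_conc: float,
                      s_max: float = 37.0) -> MixingLine:
    """Connect a river endmember at salinity 0 to an ocean endmember at
    ``s_max``."""
    return MixingLine(river_conc=river_conc, ocean_conc=ocean_conc,
                      s_max=s_max)


def annual_mixing_lines(river: pd.DataFrame, conc_col: str,
                        ocean_conc: float = 0.0,
                        s_max: float = 37.0) -> dict[int, MixingLine]:
    """Per-year mixing lines from annual river endmember concentrations (µM)."""
    return {int(row.year): build_mixing_line(getattr(row, conc_col),
                                             ocean_conc, s_max)
            for row in river.itertuples()}


def residuals(samples: pd.DataFrame, line: MixingLine,
              value_col: str = "dip_uM",
              salinity_col: str = "salinity") -> pd.DataFrame:
    """Observed minus mixing-line prediction for each sample."""
    s = samples[salinity_col].to_numpy(dtype=float)
    if (s < 0).any() or (s > line.s_max).any():
        raise ConfigurationError(
            f"salinity outside [0, {line.s_max:g}] — run QC first")
    out = samples.copy()
    out["predicted_uM"] = line.predict(s)
    out["residual_uM"] = out[value_col] - out["predicted_uM"]
    return out


def classify_dip_residual(samples: pd.DataFrame, dip_line: MixingLine,
                          tdp_line: MixingLine,
                          value_col: str = "dip_uM",
                          salinity_col: str = "salinity") -> pd.Series:
    """Three-way DIP classification against the nested DIP and TDP lines.

    ``above_both``: observed > TDP prediction; ``above_dip_below_tdp``:
    DIP prediction < observed <= TDP prediction; ``below_dip``: observed <=
    DIP prediction. The classes partition every sample set.
    """
    for s_check in (0.0, dip_line.s_max):
        if tdp_line.predict(s_check) < dip_line.predict(s_check):
            raise ConfigurationError(
                "TDP line must lie at or above the DIP line at every salinity")
    if tdp_line.s_max != dip_line.s_max:
        raise ConfigurationError("DIP and TDP lines must share s_max")
    s = samples[salinity_col].to_numpy(dtype=float)
    obs = samples[value_col].to_numpy(dtype=float)
    pred_dip = dip_line.predict(s)
    pred_tdp = tdp_line.predict(s)
    cls = np.where(obs > pred_tdp, "above_both",
                   np.where(obs > pred_dip, "above_dip_below_tdp",
                            "below_dip"))
    return pd.Series(cls, index=samples.index, name="dip_class")


def fraction_above(samples: pd.DataFrame, line: MixingLine,
                   value_col: str = "dip_uM",
                   salinity_col: str = "salinity") -> float:
    """Proportion of samples strictly above the line (on-line values count
    as not above)."""
    if len(samples) == 0:
        raise InsufficientDataError("fraction_above needs at least 1 sample")
    pred = line.predict(samples[salinity_col].to_numpy(dtype=float))
    return float((samples[value_col].to_numpy(dtype=float) > pred).mean())


@dataclass
class LnRegressionResult:
    """OLS of ln concentration on salinity."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r2": self.r2, "p_value": self.p_value, "n": self.n}


def ln_salinity_regression(samples: pd.DataFrame, value_col: str,
                           salinity_col: str = "salinity"
                           ) -> LnRegressionResult:
    """Linear regression of ln(value) on salinity.

    ``value_col`` should be a detection-limit-offset column (``din_ln_uM``,
    ``dip_ln_uM`` or their ratio) so the log is finite everywhere.
    """
    if len(samples) < 3:
        raise InsufficientDataError("ln regression needs at least 3 samples")
    s = samples[salinity_col].to_numpy(dtype=float)
    if np.allclose(s, s[0]):
        raise DegenerateInputError("salinity has zero variance")
    vals = samples[value_col].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ConfigurationError(
            f"{value_col} must be strictly positive (apply offset_for_ln)")
    fit = sm.OLS(np.log(vals), sm.add_constant(s)).fit()
    r2 = float(fit.rsquared)
    return LnRegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r2=r2 if np.isfinite(r2) else 0.0,
        p_value=float(fit.pvalues[1]), n=len(samples))
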