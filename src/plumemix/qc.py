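"""Compilation criteria and quality filters for surface bottle samples.

Filters enforce the compilation window (0-5 m depth, 1985-2019, the study
bounding box), require a salinity value in [0, 37] ppt, and exclude extreme
nutrient values (DIN > 110 uM or DIP > 8 uM). Each excluded record is
attributed to exactly one reason — the first failing rule in a fixed order —
so the exclusion report is deterministic and reconciles exactly with the
input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnitError

__all__ = [
    "QCConfig", "QCReport", "filter_samples", "convert_units",
    "offset_for_ln", "din_dip_ratio", "three_sd_diagnostic",
]

ATOMIC_MASS_N = 14.0067
ATOMIC_MASS_P = 30.9738

#: exclusion reasons in attribution order (first failing rule wins)
REASONS = ("depth", "date", "bbox", "salinity", "missing_nutrient",
           "din_max", "dip_max")


@dataclass
class QCConfig:
    """Quality-control thresholds; ranges are closed intervals, nutrient
    thresholds are strict (exclude only values strictly greater)."""

    depth_range: tuple[float, float] = (0.0, 5.0)
    date_range: tuple[str, str] = ("1985-01-01", "2019-12-31")
    bbox: tuple[float, float, float, float] = (-98.0, -79.0, 22.5, 31.0)
    salinity_range: tuple[float, float] = (0.0, 37.0)
    dip_max: float = 8.0
    din_max: float = 110.0
    dl_din: float = 0.05
    dl_dip: float = 0.03

    def __post_init__(self) -> None:
        if self.dl_din <= 0:
            raise ConfigurationError("dl_din must be positive")
        if self.dl_dip <= 0:
            raise ConfigurationError("dl_dip must be positive")
        if self.dip_max <= self.dl_dip:
            raise ConfigurationError("dip_max must exceed dl_dip")
        if self.din_max <= self.dl_din:
            raise ConfigurationError("din_max must exceed dl_din")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QCReport:
    """Record-count accounting for one filtering pass."""

    n_input: int
    n_retained: int
    excluded: dict[str, int] = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + sum(self.excluded.values())

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "excluded": dict(self.excluded)}


def filter_samples(samples: pd.DataFrame,
                   qc: QCConfig | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Apply all compilation criteria; return (retained, report).

    Rule order: depth -> date -> bbox -> salinity (missing or outside
    [0, 37]) -> missing nutrient -> DIN threshold -> DIP threshold.
    Boundary values on closed ranges are retained; a nutrient exactly at its
    threshold is retained ("above" means strictly greater).
    """
    qc = qc or QCConfig()
    df = samples.reset_index(drop=True)
    n = len(df)
    dates = pd.to_datetime(df["date"], errors="coerce")
    d0, d1 = pd.Timestamp(qc.date_range[0]), pd.Timestamp(qc.date_range[1])
    lon_min, lon_max, lat_min, lat_max = qc.bbox

    depth = pd.to_numeric(df["depth_m"], errors="coerce")
    sal = pd.to_numeric(df["salinity"], errors="coerce")
    din = pd.to_numeric(df["din_uM"], errors="coerce")
    dip = pd.to_numeric(df["dip_uM"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")

    fails = {
        "depth": ~(depth.between(*qc.depth_range)),
        "date": ~((dates >= d0) & (dates <= d1)),
        "bbox": ~(lon.between(lon_min, lon_max) & lat.between(lat_min, lat_max)),
        "salinity": ~(sal.between(*qc.salinity_range)),
        "missing_nutrient": din.isna() | dip.isna(),
        "din_max": din > qc.din_max,
        "dip_max": dip > qc.dip_max,
    }

    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    for name in REASONS:
        mask = fails[name].fillna(True) if name != "missing_nutrient" else fails[name]
        reason = reason.mask(reason.isna() & mask, name)

    retained = df.loc[reason.isna()].reset_index(drop=True)
    counts = {name: int((reason == name).sum()) for name in REASONS}
    report = QCReport(n_input=n, n_retained=len(retained), excluded=counts)
    assert report.reconciles()
    return retained, report


_UNIT_ALIASES = {
    "uM": "uM", "µM": "uM", "umol/L": "uM", "µmol/L": "uM",
    "mg/L-N": "mg/L-N", "mg/L-P": "mg/L-P",
}


def convert_units(value: float, unit: str) -> float:
    """Convert a concentration to µM.

    µM and µmol/L pass through; mg/L as N or P converts via
    µM = mg/L * 1000 / atomic mass (N 14.0067, P 30.9738).
    """
    try:
        canonical = _UNIT_ALIASES[unit]
    except KeyError:
        raise UnitError(f"unknown concentration unit {unit!r}") from None
    if canonical == "uM":
        return float(value)
    mass = ATOMIC_MASS_N if canonical == "mg/L-N" else ATOMIC_MASS_P
    return float(value) * 1000.0 / mass


def offset_for_ln(samples: pd.DataFrame,
                  qc: QCConfig | None = None) -> pd.DataFrame:
    """Add detection-limit offsets to ALL samples ahead of ln transforms.

    Appends ``din_ln_uM = din_uM + dl_din`` and ``dip_ln_uM = dip_uM +
    dl_dip`` (0.05 and 0.03 µM by default); the offset columns are strictly
    positive, so logs and ratios are always finite.
    """
    qc = qc or QCConfig()
    out = samples.copy()
    out["din_ln_uM"] = out["din_uM"] + qc.dl_din
    out["dip_ln_uM"] = out["dip_uM"] + qc.dl_dip
    return out


def din_dip_ratio(samples: pd.DataFrame) -> pd.Series:
    """Molar DIN:DIP from the offset columns (finite by construction)."""
    if "din_ln_uM" not in samples or "dip_ln_uM" not in samples:
        raise ConfigurationError(
            "offset columns missing; call offset_for_ln first")
    return samples["din_ln_uM"] / samples["dip_ln_uM"]


def three_sd_diagnostic(samples: pd.DataFrame) -> dict:
    """Report (never apply) mean + 3 SD reference thresholds for DIN and DIP.

    The operational exclusion thresholds are fixed constants; this diagnostic
    shows where a recomputed three-standard-deviation rule would sit on the
    data at hand.
    """
    out = {}
    for col in ("din_uM", "dip_uM"):
        vals = pd.to_numeric(samples[col], errors="coerce").dropna()
        out[col] = float(vals.mean() + 3.0 * vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return out
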