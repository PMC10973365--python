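"""End-to-end orchestration: synth/ingest -> QC -> regions -> analyses.

One configuration (YAML/JSON-friendly dict or :class:`PipelineConfig`)
drives every stage; all randomness flows from the single pipeline seed. Each
stage writes its outputs as CSV/JSON into the output directory, and a run
manifest records the configuration hash, per-stage row counts, and
timestamps. Re-running with an identical configuration and seed reproduces
identical output files (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import changepoint as cp
from . import correlations as corr
from . import io as pio
from . import mixing, qc, regions, synthetic, trends
from .errors import ConfigurationError

log = logging.getLogger("plumemix")

__all__ = ["PipelineConfig", "EndmemberConfig", "RunManifest", "run_pipeline"]

MOLAR_MASS_UM_PER_MGL_P = 1000.0 / qc.ATOMIC_MASS_P


@dataclass
class EndmemberConfig:
    """Mixing-line endmembers (µM at salinity 0 and at ``s_max``).

    The ocean endmember convention is configurable per nutrient: the
    detection limit (the minimum resolvable ocean concentration) or zero.
    Defaults use zero, which reproduces the printed DIP and TDP line slopes.
    """

    din_river: float = 103.0
    dip_river: float = 2.2
    tdp_river: float = 3.3
    din_ocean: float = 0.0
    dip_ocean: float = 0.0
    tdp_ocean: float = 0.0
    s_max: float = 37.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    """Exactly one of ``synthetic=True`` or all four real input paths."""

    outdir: str = "plumemix_out"
    seed: int = 0
    synthetic: bool = True
    synth: synthetic.SyntheticConfig | None = None
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    regions: regions.RegionConfig = field(default_factory=regions.RegionConfig)
    endmembers: EndmemberConfig = field(default_factory=EndmemberConfig)
    changepoint_method: str = "enumerate"
    changepoint_iters: int = 20000
    samples_path: str | None = None
    river_path: str | None = None
    bathymetry_path: str | None = None
    hypoxia_path: str | None = None

    def __post_init__(self) -> None:
        paths = (self.samples_path, self.river_path, self.bathymetry_path,
                 self.hypoxia_path)
        if self.synthetic:
            if any(p is not None for p in paths):
                raise ConfigurationError(
                    "synthetic mode and real input paths are mutually exclusive")
            if self.synth is None:
                self.synth = synthetic.SyntheticConfig(seed=self.seed)
        else:
            missing = [name for name, p in zip(
                ("samples_path", "river_path", "bathymetry_path",
                 "hypoxia_path"), paths) if p is None]
            if missing:
                raise ConfigurationError(
                    f"real-data mode requires paths: {', '.join(missing)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = synthetic.SyntheticConfig.from_dict(d["synth"])
        if "qc" in d and isinstance(d["qc"], dict):
            sub = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["qc"].items()}
            d["qc"] = qc.QCConfig(**sub)
        if "regions" in d and isinstance(d["regions"], dict):
            sub = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["regions"].items()}
            d["regions"] = regions.RegionConfig(**sub)
        if "endmembers" in d and isinstance(d["endmembers"], dict):
            d["endmembers"] = EndmemberConfig(**d["endmembers"])
        return cls(**d)

    def to_dict(self) -> dict:
        out = {
            "outdir": self.outdir, "seed": self.seed,
            "synthetic": self.synthetic,
            "synth": self.synth.to_dict() if self.synth else None,
            "qc": self.qc.to_dict(), "regions": self.regions.to_dict(),
            "endmembers": self.endmembers.to_dict(),
            "changepoint_method": self.changepoint_method,
            "changepoint_iters": self.changepoint_iters,
        }
        for key in ("samples_path", "river_path", "bathymetry_path",
                    "hypoxia_path"):
            out[key] = getattr(self, key)
        return out


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    row_counts: dict[str, int]
    started: str
    finished: str = ""
    status: str = "RUNNING"

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _regional_annual_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Long-format annual means (region, variable, year, value, n) for the
    three nutrient variables over all four regional subsets."""
    frames = []
    masks = {
        "all": np.ones(len(samples), dtype=bool),
        "hypoxic": samples["is_hypoxic"].to_numpy(),
        "shelf": samples["is_shelf"].to_numpy(),
        "offshore": samples["is_offshore"].to_numpy(),
    }
    for region, mask in masks.items():
        sub = samples.loc[mask]
        if sub.empty:
            continue
        for var in ("din_uM", "dip_uM", "din_dip"):
            try:
                am = trends.annual_means(sub, var)
            except Exception:  # too few years in a sparse subset
                continue
            am = am.assign(region=region, variable=var)
            frames.append(am)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order, writing outputs under ``config.outdir``.

    Any stage error halts the run; outputs already written are retained and
    a FAILED marker file names the stage and cause.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, row_counts={},
        started=datetime.now(timezone.utc).isoformat())
    stage = "setup"
    try:
        # --- stage 1: synthesize or ingest -------------------------------
        stage = "ingest"
        if config.synthetic:
            sc = config.synth
            samples = synthetic.generate_surface_samples(sc)
            river = synthetic.generate_river_series(sc)
            grid = synthetic.generate_bathymetry(sc)
            hypoxia = synthetic.generate_hypoxic_series(sc, river)
        else:
            samples = pio.read_samples_csv(config.samples_path)
            river = pd.read_csv(config.river_path)
            grid = regions.load_bathymetry_grid(config.bathymetry_path)
            hypoxia = pd.read_csv(config.hypoxia_path)
        pio.write_csv(samples, outdir / "samples_raw.csv")
        pio.write_csv(river, outdir / "river_annual.csv")
        pio.grid_to_csv(grid, outdir / "bathymetry.csv")
        pio.write_csv(hypoxia, outdir / "hypoxia_annual.csv")
        manifest.row_counts["samples_raw"] = len(samples)
        manifest.row_counts["river_annual"] = len(river)
        manifest.row_counts["hypoxia_annual"] = len(hypoxia)
        log.info("ingest: %d samples, %d river years", len(samples), len(river))

        # --- stage 2: QC --------------------------------------------------
        stage = "qc"
        retained, report = qc.filter_samples(samples, config.qc)
        (outdir / "qc_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        manifest.row_counts["samples_qc"] = len(retained)
        log.info("qc: retained %d of %d", report.n_retained, report.n_input)

        # --- stage 3: regions --------------------------------------------
        stage = "regions"
        located = regions.attach_bottom_depth(retained, grid)
        located = regions.classify_region(located, config.regions)
        located = qc.offset_for_ln(located, config.qc)
        located["din_dip"] = qc.din_dip_ratio(located)
        pio.write_csv(located, outdir / "samples_qc_regions.csv")
        manifest.row_counts["samples_regions"] = len(located)

        # --- stage 4: trends ---------------------------------------------
        stage = "trends"
        regional = _regional_annual_means(located)
        pio.write_csv(regional, outdir / "annual_means.csv")
        trend_rows = []
        for (region, var), grp in regional.groupby(["region", "variable"]):
            if len(grp) < 3:
                continue
            res = trends.fit_trend(grp[["year", "value"]], variable=var)
            row = res.to_dict()
            row["region"] = region
            trend_rows.append(row)
        trends_df = pd.DataFrame(trend_rows)
        pio.write_csv(trends_df, outdir / "trends.csv")
        manifest.row_counts["trends"] = len(trends_df)

        # --- stage 5: changepoint ----------------------------------------
        stage = "changepoint"
        cp_summaries = {}
        cp_tables = []
        for var in ("din_uM", "dip_uM"):
            ser = regional.query("region == 'all' and variable == @var")
            ser = ser[["year", "value"]]
            if config.changepoint_method == "mcmc":
                post = cp.changepoint_mcmc(ser, n_iter=config.changepoint_iters,
                                           seed=config.seed)
            else:
                post = cp.changepoint_enumerate(ser)
            cp_summaries[var] = post.to_dict()
            cp_tables.append(post.to_frame().assign(variable=var))
        (outdir / "changepoint_summary.json").write_text(
            json.dumps(cp_summaries, indent=2))
        pio.write_csv(pd.concat(cp_tables, ignore_index=True),
                      outdir / "changepoint_posterior.csv")
        manifest.row_counts["changepoint_vars"] = len(cp_summaries)

        # --- stage 6: mixing ---------------------------------------------
        stage = "mixing"
        em = config.endmembers
        dip_line = mixing.build_mixing_line(em.dip_river, em.dip_ocean, em.s_max)
        tdp_line = mixing.build_mixing_line(em.tdp_river, em.tdp_ocean, em.s_max)
        din_line = mixing.build_mixing_line(em.din_river, em.din_ocean, em.s_max)
        resid = mixing.residuals(located, dip_line, value_col="dip_uM")
        resid["dip_class"] = mixing.classify_dip_residual(
            resid, dip_line, tdp_line)
        pio.write_csv(resid, outdir / "dip_residuals.csv")
        mixing_summary = {
            "dip_line": {"slope": dip_line.slope, "intercept": dip_line.intercept},
            "tdp_line": {"slope": tdp_line.slope, "intercept": tdp_line.intercept},
            "din_line": {"slope": din_line.slope, "intercept": din_line.intercept},
            "fraction_dip_above": mixing.fraction_above(located, dip_line,
                                                        value_col="dip_uM"),
            "fraction_din_above": mixing.fraction_above(located, din_line,
                                                        value_col="din_uM"),
            "class_counts": resid["dip_class"].value_counts().to_dict(),
            "ln_regressions": {
                var: mixing.ln_salinity_regression(located, var).to_dict()
                for var in ("din_ln_uM", "dip_ln_uM", "din_dip")},
        }
        (outdir / "mixing_summary.json").write_text(
            json.dumps(mixing_summary, indent=2))
        manifest.row_counts["dip_residuals"] = len(resid)

        # --- stage 7: correlations ---------------------------------------
        stage = "correlations"
        cmat = corr.correlation_matrix(river, regional, hypoxia)
        pio.write_csv(cmat, outdir / "correlations.csv")
        manifest.row_counts["correlations"] = len(cmat)

        manifest.status = "OK"
    except Exception as exc:
        manifest.status = "FAILED"
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc!r}\n")
        manifest.finished = datetime.now(timezone.utc).isoformat()
        (outdir / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2))
        raise
    manifest.finished = datetime.now(timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2))
    return manifest
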