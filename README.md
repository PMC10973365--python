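# plumemix

Spatiotemporal analysis of surface nutrients along a river-to-ocean salinity
gradient, built for the Mississippi/Atchafalaya River (MAR) plume in the
Northern Gulf of Mexico but reusable for any two-endmember estuarine system.

The package is aimed at marine biogeochemists who compile surface
bottle-sample data (salinity, dissolved inorganic nitrogen DIN = NO₂⁻+NO₃⁻,
dissolved inorganic phosphorus DIP) from heterogeneous archives and want a
tested, reproducible pipeline for:

- **QC / compilation** — 0–5 m depth, 1985–2019, study bounding box,
  salinity required in 0–37 ppt, exclusion of extreme values
  (DIN > 110 µM, DIP > 8 µM), unit conversion to µM, detection-limit
  offsets (0.05 µM DIN, 0.03 µM DIP) ahead of log transforms;
- **regional subsetting** — bottom depth attached from a bathymetry grid;
  hypoxic (fixed shallow box, depth < 60 m) ⊂ shelf (< 200 m) vs offshore
  (> 200 m);
- **temporal trends** — OLS of annual means on years since 1985,
  Durbin–Watson autocorrelation diagnostics, iterative Cochrane–Orcutt
  correction, Breusch–Pagan heteroscedasticity test;
- **Bayesian changepoint detection** — a single level shift δ·1(t>τ) on top
  of a shared linear trend (standardized series, common variance), with an
  exact-enumeration posterior and a Gibbs sampler; a diffuse τ posterior is
  the evidence that monotonic trend analysis is appropriate;
- **conservative mixing-line residuals** — the two-endmember line
  C(s) = C_river + (C_ocean − C_river)·s/s_max, per-sample residuals,
  three-way classification of DIP against the nested DIP and TDP lines,
  and ln-concentration vs salinity regressions;
- **correlation analysis** — Pearson grids of river discharge/
  concentrations/loads × regional annual nutrient means × annual hypoxic
  area.

A seeded synthetic-data generator reproduces the statistical structure the
analysis assumes (DIN declining faster with salinity than DIP, a
configurable fraction of DIP above the conservative line bounded by the TDP
line, a linear DIP trend with AR(1) interannual noise, detection-limit
censoring, rare extreme outliers), so every stage is testable without the
original compiled dataset, which is not publicly redistributable.

## The model at the core

For a conservative tracer mixing between a river endmember (concentration
C₀ at salinity 0) and an ocean endmember (C₃₇ at 37 ppt), concentration is
linear in salinity:

    C(s) = C₀ + (C₃₇ − C₀)/37 · s

With the long-term mean MAR endmembers, DIP = 2.2 µM and TDP = 3.3 µM
against a ≈0 µM ocean endmember, giving the lines y = −0.059x + 2.2 and
y = −0.089x + 3.3 (µM vs ppt). A sample above the line implies a nutrient
source beyond river dilution; below implies net removal (e.g. uptake). DIP
values between the DIP and TDP lines are explainable by conversion of
riverine organic P; values above both lines require additional sources.

## Worked example

```python
import plumemix as pm

cfg = pm.SyntheticConfig(seed=42)            # 35 years x 300 samples/yr
samples = pm.generate_surface_samples(cfg)
retained, report = pm.filter_samples(samples)
print(report.to_dict())

dip = pm.fit_trend(pm.annual_means(retained, "dip_uM"), "dip_uM")
din = pm.fit_trend(pm.annual_means(retained, "din_uM"), "din_uM")
post = pm.changepoint_enumerate(
    pm.annual_means(retained, "dip_uM")[["year", "value"]])

dip_line = pm.build_mixing_line(2.2, 0.0, 37.0)
frac = pm.fraction_above(retained, dip_line, value_col="dip_uM")
```

Output (seed 42):

```
{'n_input': 10500, 'n_retained': 10440,
 'excluded': {'depth': 0, 'date': 0, 'bbox': 0, 'salinity': 0,
              'missing_nutrient': 0, 'din_max': 34, 'dip_max': 26}}
DIP trend: slope=0.0189 uM/yr  p=3.74e-05  r2=0.41  DW=2.19
DIN trend: slope=-0.0162 uM/yr  p=0.795  r2=0.00  DW=1.80
changepoint: {'tau_map': 2015, 'ci95': [1986, 2016], 'significant': False}
DIP line: slope=-0.059, intercept=2.2
fraction above DIP line: 0.612
```

Reading the numbers: the 60 excluded records are exactly the generator's
injected outliers (the extreme-value rules caught all of them and nothing
else); the annual-mean DIP trend recovers the configured 0.02 µM/yr and is
significant, while DIN shows no trend; the changepoint 95% interval spans
31 of 35 years — diffuse, so monotonic trend analysis is appropriate; and
61% of DIP samples sit above the long-term-mean conservative line (the
configured excess fraction is 0.5 per year against the year-specific line;
the rising annual level pushes later years above the fixed long-term line).

The same pipeline runs end-to-end from one config:

```
plumemix run --seed 42 --outdir out/        # or: plumemix run --config cfg.yaml
plumemix synth / qc / regions / trends / changepoint / mixing / correlate
```

writing per-stage CSV/JSON outputs plus a run manifest (config hash, row
counts per stage); identical config + seed reproduces byte-identical
outputs.

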