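# Methods

This note documents the statistical models, the synthetic study conditions,
the numerical choices, and the limitations of the `plumemix` pipeline.

## Quality control and compilation

Records pass, in a fixed order: collection depth in [0, 5] m → date in
[1985-01-01, 2019-12-31] → position inside lon [−98, −79], lat [22.5, 31] →
salinity present and in [0, 37] ppt → DIN and DIP present → DIN ≤ 110 µM →
DIP ≤ 8 µM. Each excluded record is attributed to the *first* failing rule,
which makes the exclusion report deterministic and lets counts reconcile
exactly (`n_input = n_retained + Σ exclusions`). Range bounds are closed;
the nutrient thresholds are strict ("above" means strictly greater), so a
sample at exactly 110 µM DIN is retained.

The 110/8 µM thresholds are fixed operational constants motivated as
roughly three standard deviations above the mean of the original
compilation. They are deliberately *not* recomputed from the data at hand —
a recomputed 3-SD rule would drift with every dataset — but
`three_sd_diagnostic` reports where such a rule would sit, for comparison.

Unit conversion to µM uses atomic masses N = 14.0067, P = 30.9738
(µM = mg/L × 1000 / mass). Before any log transform, detection-limit
offsets are added to **all** samples (not only zeros): 0.05 µM to DIN,
0.03 µM to DIP. The offset columns are strictly positive, so ln
transforms and DIN:DIP ratios are finite everywhere; the molar ratio of an
all-zero sample is therefore 0.05/0.03 ≈ 1.67 by construction.

## Regional subsetting

Bottom depth is looked up from a regular lat/lon grid by nearest cell
center; coordinates outside the grid extent (centers ± half a cell) raise
an error carrying the coordinate. Grids supplied with negative (positive-up)
ocean depths are sign-normalized on load.

Membership: hypoxic ⟺ inside lon [−95, −88], lat [27, 29] *and* bottom
depth < 60 m; shelf ⟺ depth < 200 m; offshore ⟺ depth > 200 m. Hypoxic is
a subset of shelf; flags for all three are returned along with a primary
label (most specific membership). A depth of exactly 200 m satisfies
neither strict inequality; such samples go to the shelf and a boundary
warning is emitted — a conservative, documented convention that affects a
measure-zero set on real grids.

## Trend analysis

Annual means are simple arithmetic means over all retained samples in a
calendar year (no cruise weighting — the provenance needed for weighting is
not part of the data model). Trends are OLS of annual means on
(year − 1985), so intercepts are concentrations at the start of the study
window. Autocorrelation is diagnosed with the Durbin–Watson statistic
DW = Σ(eₜ−eₜ₋₁)²/Σeₜ²; significance uses the large-sample normal
approximation under the null (mean 2, variance 4/n) at α = 0.05, with a
residual-bootstrap alternative available (exact DW critical values depend
on the design matrix; for a single regressor at n ≈ 35 the normal
approximation's size is within a couple of points of nominal, which the
test suite checks by simulation).

When DW flags autocorrelation, the classic Cochrane–Orcutt iteration runs:
estimate ρ by lag-1 OLS of the residuals, quasi-difference
(yₜ − ρyₜ₋₁ on xₜ − ρxₜ₋₁, dropping the first observation), refit, repeat
until |Δρ| < 1e−6 (at most 100 iterations; non-convergence is flagged and
the last iterate returned). The corrected intercept is mapped back by
dividing by (1 − ρ); the slope needs no rescaling. Both the uncorrected and
corrected fits are always stored. Prais–Winsten rescaling of the first
observation is intentionally not used; the classic form is what the
workflow names. Heteroscedasticity is diagnosed with the Breusch–Pagan LM
test (n·R² of squared residuals on the regressor, χ² with 1 df); constant
residuals return LM = 0 by convention.

## Bayesian changepoint model

Both year and value are standardized (mean 0, sample SD 1). The default
model is an intervention model: a level shift riding on a common linear
trend,

    yₜ = a + b·xₜ + δ·zₜ(τ) + εₜ,   εₜ ~ N(0, σ²),

where zₜ(τ) = −½ for t ≤ τ and +½ after (the antisymmetric coding makes
reversing the series exactly reverse the τ posterior). Priors: τ uniform
over interior candidates (at least two points per side), coefficients
N(0, 10²), σ² ~ Inverse-Gamma(0.1, 0.1). A smooth monotonic trend is
absorbed by the shared slope b, leaving the τ posterior diffuse; an abrupt
break in level loads on δ and concentrates it. This is exactly the
question the pipeline asks — *is a monotonic fit appropriate, or is there a
break?* Two alternative mean structures are exposed: `constant` (the
classic two-normal-means model; note a strong smooth trend also
concentrates its posterior mid-series, so it answers "is there a contrast
between early and late years", not "is there a break beyond the trend") and
`linear` (independent slopes per segment, sensitive to slope breaks). The
trade-off is intrinsic: a trend strong enough to be reliably significant
carries nearly the same half-series mean contrast as a 2-SD step, so a
detector that ignores trends necessarily loses power against pure steps —
at n = 35 the step indicator and the trend regressor correlate at ≈ 0.87.

Two routes to the posterior:

- **Enumeration (exact).** Given σ², the mean coefficients marginalize in
  closed form (matrix determinant lemma / Woodbury, p ≤ 3). The remaining
  one-dimensional σ² integral against the Inverse-Gamma prior is evaluated
  by 200-node Gauss–Legendre quadrature on ln σ² over [−12, 12] — the
  integrand is smooth and, for standardized data, negligible outside this
  range. The posterior over τ is then normalized directly; it sums to 1 to
  machine precision.
- **Gibbs sampler.** Full conditionals: multivariate normal for the
  coefficients, Inverse-Gamma for σ², and the exact discrete conditional
  for τ. Default 20 000 iterations, 2 000 burn-in, seeded. The test suite
  verifies total-variation agreement with enumeration below 0.05.

Summaries: the posterior mode year, and the smallest set of consecutive
candidate years holding ≥ 95% of the mass (ties broken toward the densest,
then leftmost window). The changepoint is called *significant* when that
95% set covers less than 30% of the candidate positions (a configurable
convention); otherwise the series is treated as monotonic downstream.

## Conservative mixing lines and residuals

A line connects the river endmember at salinity 0 to the ocean endmember at
s_max = 37 ppt; predictions are exact at both endmembers (the ocean
endmember is pinned against floating-point drift). Residual = observed −
predicted. DIP classification against the nested DIP and TDP lines:
`above_both` (observed > TDP prediction), `above_dip_below_tdp`
(DIP < observed ≤ TDP), `below_dip` (observed ≤ DIP); the three classes
partition any sample set, and non-nested line pairs are rejected up front
(for lines sharing s_max it suffices to check both endpoints). On-line
values count as *not* above (strict inequality), matching the "exceeds the
line" reading. `fraction_above` uses the same strict convention.

The ocean endmember convention deserves a note: the DIP line printed as
y = −0.059x + 2.2 is consistent with an ocean endmember of either 0 or the
0.03 µM detection limit (both round to −0.059), but the TDP line
y = −0.089x + 3.3 is consistent only with ≈ 0 (3.3/37 = 0.0892; with a
0.03 endmember the slope would round to −0.088). The package default is
therefore a zero ocean endmember, with the endmember configurable per line.

Per-year endmember lines (from annual river means) are supported alongside
the long-term-mean default. ln-concentration vs salinity regressions are
OLS of ln(value) on salinity and require the detection-limit-offset columns
so the log is finite.

## Synthetic study conditions

The generator emulates the statistical structure of the compiled data, not
the physics of the plume. Defaults (all in `SyntheticConfig`):

| parameter | default | meaning |
|---|---|---|
| years | 1985–2019 | 35 annual cohorts |
| samples_per_year | 300 | ≈10⁴ samples total |
| river_din0 | 103 µM | DIN river endmember (DIN:DIP ≈ 47 at salinity 0) |
| river_dip0 / river_tdp0 | 2.2 / 3.3 µM | DIP and TDP river endmembers |
| ocean_salinity | 37 ppt | ocean endmember salinity |
| din_loss_rate | 0.12 ppt⁻¹ | extra exponential DIN loss beyond dilution |
| p_excess | 0.5 | probability a DIP draw lies above the DIP line |
| dip_trend | 0.02 µM yr⁻¹ | linear trend of the annual DIP level |
| rho | 0.15 | AR(1) coefficient of annual deviations ("minimal" autocorrelation) |
| annual_sd | 0.2 µM | stationary SD of the annual DIP level deviations |
| annual_cv_din | 0.25 | relative SD of the multiplicative annual DIN level |
| noise_cv | 0.3 | per-sample lognormal noise CV on DIN |
| outlier_rate | 0.005 | probability of an injected extreme value |
| summer_fraction | 0.6 | fraction of dates drawn in June–August |

Salinity comes from a two-component Beta mixture (45% plume-weighted
Beta(1.2, 3.5), 55% offshore-weighted Beta(5, 1.6), scaled to [0, 37]), so
both shelf and offshore regions contain nearly the full salinity range.
DIN follows the dilution line times exp(−loss·s) times unit-mean lognormal
noise, scaled by a multiplicative annual level (1 + AR(1) deviation) that
keeps the field positive and proportional to the dilution line. DIP is
drawn uniformly below the year's DIP line with probability 1 − p_excess and
uniformly between the DIP and TDP lines otherwise; the annual DIP level
(trend + AR(1) deviation, in µM on the annual mean) is applied as a
multiplicative factor on the whole DIP geometry — draws and lines together
— normalized by the analytic expected baseline, so the expected annual-mean
slope equals `dip_trend` exactly while no draw ever exceeds the year's TDP
line. (An additive shift was rejected: it either clips at zero, biasing the
slope low by ≈25%, or violates non-negativity.) The year-specific line
predictions are emitted as `truth_` bookkeeping columns.

The noise scales are calibrated to the qualitative record the pipeline is
designed for: a DIP trend that is statistically robust yet carries
interannual variability of the same order as the 35-year signal (annual-sd
0.2 µM vs total rise 0.7 µM, trend r² ≈ 0.4–0.5), a highly variable DIN
series with no trend, and weak annual autocorrelation. Non-outlier DIN is
truncated at 110 µM and DIP draws are bounded below 8 µM by construction
(TDP endmember < 8 is enforced at config validation), so the *only* records
the extreme-value QC rules remove are the injected outliers — which makes
the generator's outlier bookkeeping an exact oracle for the QC counts.
Detection-limit censoring sets values below 0.05/0.03 µM to zero.

River series: each base variable (discharge m³/yr; DIN/DON/DIP/DOP/sediment
mg/L) follows base·(1 + trend%·t)·(1 + AR(1) deviation); TDN = DIN + DON
and TDP = DIP + DOP are computed, so organic ≤ total holds by construction.
Loads (kg/yr) are concentration × discharge / 1000. Bathymetry is a smooth
monotone shelf-to-basin profile (cubic in latitude, 5 m to 3500 m) with a
mild longitudinal modulation; depth increases strictly offshore at every
longitude. Hypoxic area is a + b·(DIN load) + Gaussian noise, truncated at
zero. All randomness flows from one seed through named substreams
(surface / river / bathymetry / hypoxia), so artifacts regenerate
independently and byte-identically.

What the generator does **not** emulate: circulation, plume geometry,
seasonality beyond the summer sampling bias, cruise clustering,
measurement-method heterogeneity between archives, or spatial correlation
of concentrations at fixed salinity. Passing tests demonstrate that the
pipeline recovers known parameters under the stated statistical structure —
not that the structure captures every feature of the real compilation.

## Correlation analysis

Pearson product-moment r with the two-sided t-transform p-value (n − 2 df),
α = 0.05 per test, pairwise deletion of missing years per comparison (not
listwise). No multiple-testing correction enters the significance flags,
matching the per-test reporting convention of the workflow; a
Benjamini–Hochberg adjusted column (`p_bh`) is additionally emitted for
users who want family-wise control. Zero-variance inputs are flagged
degenerate rather than crashing the grid.

## Pipeline and provenance

`run_pipeline` executes synth/ingest → QC → regions → {trends, changepoint,
mixing, correlations}, writing every stage output as CSV/JSON plus a
manifest (SHA-256 config hash, seed, per-stage row counts, timestamps). A
stage failure halts the run, retains partial outputs, and writes a FAILED
marker naming the stage. Outputs are written at full precision; rounding
(e.g. 3 decimal places for line slopes) is a display concern only.

## Problem sizes used in the test suite

Unit and acceptance tests run the default conditions (35 years × 300
samples/yr) with 100–300 replicates for rate estimates, 1000 replicates for
test-size checks at n = 35, n = 200 years for AR(1) recovery, and 20 000
Gibbs iterations for sampler-vs-enumeration agreement; these sizes put
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the whole suite under a minute of compute.

## Known limitations

- The Durbin–Watson normal approximation ignores the design matrix; its
  exact size at n = 35 is ≈6%, not 5% (the bootstrap alternative conditions
  on the residuals instead).
- Cochrane–Orcutt's ρ̂ carries the usual O(1/n) downward bias; at n = 35
  and weak ρ this is within the reported uncertainty.
- With undetected autocorrelation (DW has limited power below ρ ≈ 0.4 at
  n = 35), OLS slope standard errors are mildly optimistic; at the default
  ρ = 0.15 the 95% CI coverage of the trend slope is ≈0.95.
- The changepoint significance convention (95% set < 30% of candidates) is
  a calibration choice, not a formal test; its behavior under the three
  mean structures is characterized in the test suite.
- The two-endmember framework attributes all deviation from the line to
  sources/sinks; a real system with more than two water masses violates
  this premise.
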