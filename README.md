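# dsmtools

Density surface modelling (DSM) of shipboard line-transect surveys for
small cetaceans — striped, bottlenose and common dolphins in the reference
application — estimating spatial distribution and total abundance from
effort tracks, sighting records and environmental covariate rasters.

Line-transect surveys detect only a fraction of the animals present, and
that fraction decays with perpendicular distance from the trackline.  The
package implements the standard two-stage DSM estimator:

1. **Detection.**  A detection function `g(x)` (half-normal
   `exp(−x²/2σ²)` or hazard-rate `1 − exp(−(x/σ)^−b)`) is fitted to pooled
   perpendicular distances truncated at `w`, with Beaufort sea state and
   log cluster size on the scale, `σ_i = exp(β·z_i)`; candidates are
   selected by AIC and checked with Kolmogorov–Smirnov and
   Cramér–von Mises tests.  Each cluster gets a detection probability
   `p_i = (1/w)∫₀^w g(u; z_i) du`.
2. **Spatial model.**  Effort is cut into ~1 km segments with searched
   area `A_j = 2 w l_j`; per-segment Horvitz–Thompson abundances
   `n̂_j = Σ s_i/p_i` are modelled as
   `E[n̂_j] = A_j exp(β₀ + Σ_k f_k(z_jk))` with penalized-spline smooths of
   depth, slope, distance from coast, distance from the 200 m isobath,
   SST, CHL and a joint x/y term, a Tweedie or negative-binomial response,
   REML smoothing, and backward term selection.  The fitted surface is
   summed over a 4 km prediction grid; detection and GAM CVs combine in
   quadrature and a lognormal 95% CI is reported:
   `N̂ ∈ [N̂/C, N̂·C]`, `C = exp(1.96 √ln(1+CV²))`.

A synthetic-survey generator (rasters → inhomogeneous Poisson cluster
placement → zigzag or random-line observation with distance-dependent
thinning) provides full pipelines with known truth for verification.

## Worked example

Simulate a survey at the reference scale (~5,200 km of zigzag effort,
~150 detected clusters) and analyse it end to end:

```
$ dsmtools simulate --out demo --seed 3
{
  "n_true": 33206,
  "n_clusters_placed": 8094,
  "n_detected": 166,
  "effort_km": 5214.604491234263,
  "out": "demo"
}
```

Write a config pointing at the simulated files:

```yaml
# demo.yaml
paths:
  effort: demo/effort.csv
  sightings: demo/sightings.csv
  rasters: demo/rasters
  output: demo/out
species_models:
  pooled: {family: tweedie, terms: [depth, chl], k: {depth: 6, chl: 6}}
```

```
$ dsmtools run --config demo.yaml
{
  "pooled": {
    "N_hat": 37914.03442799162,
    "ci_low": 30258.290107497596,
    "ci_high": 47506.78248837157,
    "cv_total": 0.11546128783984197
  }
}
```

For this seed AIC selects the half-normal key with sea-state and
cluster-size covariates (p̄ ≈ 0.55, CV 0.064; with only ~166 distances the
generating hazard-rate shape is not always distinguishable); the spatial
Tweedie GAM on depth and CHL predicts 37,914 individuals against a known
truth of 33,206 — a recovery ratio of 1.14, with the 95% lognormal
interval (30,258–47,507) covering the truth.  `demo/out/` holds the full
report (`report.json`), per-segment and per-cell tables, and detection and
quantile-residual diagnostics as CSV.

Defaults reproduce the reference analysis protocol exactly: 500 m
truncation, 1 km segments, 4 km grid, half-normal/hazard-rate candidates,
backward selection at α = 0.05 (0.1 for striped dolphin).  Real surveys
use the same config with species-level models
(`striped: {family: tweedie, alpha: 0.1}, ...`) and their own rasters
(ESRI ASCII grids; 8-day composites dated via
`name_YYYY-MM-DD_YYYY-MM-DD.asc` file names).

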