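# Methods

`dsmtools` implements two-stage density surface modelling (DSM) of
line-transect survey data for small cetaceans: a distance-sampling
detection function corrects for imperfect detectability, and a spatial
generalized additive model (GAM) smooths detection-corrected segment
abundances over environmental covariates to yield gridded abundance
predictions with propagated uncertainty.

## Stage 1 — detection

Perpendicular distances `x_i` of detected clusters (truncated at
`w = 500 m` by default) are fitted with a half-normal
`g(x) = exp(-x² / 2σ²)` or hazard-rate `g(x) = 1 − exp(−(x/σ)^−b)` key, no
adjustment terms, `g(0) = 1` (no availability or perception-bias
correction).  Observation-level covariates enter the scale log-linearly,

    σ_i = exp(β · z_i),   z_i = (1, Beaufort sea state, log cluster size),

the multiple-covariate distance-sampling formulation.  Sea state is numeric
(ordinal treated as linear) and cluster size enters as `log s_i`; the
hazard-rate shape `b` carries no covariates and is constrained `b ≥ 1` so
the curve keeps a shoulder (a boundary estimate triggers a warning).
Detection is fitted to all species pooled, including unidentified clusters;
species enter only at the spatial stage.

Estimation maximizes the conditional likelihood `Π g(x_i)/μ(z_i)` with
`μ(z) = ∫₀^w g` (96-node Gauss–Legendre inside the optimizer; adaptive
quadrature with absolute tolerance `1e−8·w` on the public surface).  The
optimizer is L-BFGS-B restarted from three deterministic scales
(method-of-moments σ, halved, doubled).  The covariance is the inverse
numerical Hessian of the negative log-likelihood.  Candidate models
(key × covariate set) are compared by AIC on identical data and
truncation; ties go to fewer parameters.

Per-cluster detection probability is `p_i = μ(z_i)/w`; the
Horvitz–Thompson-consistent average is `p̄ = n / Σ 1/p_i` with a
delta-method CV through the parameter covariance (a transect-resampling
bootstrap is available as a cross-check; the two agree within ~20% in
tests).  Goodness of fit transforms each observation by its fitted
conditional CDF, `u_i = F_i(x_i)`, and tests uniformity by
Kolmogorov–Smirnov (asymptotic Kolmogorov distribution) and
Cramér–von Mises (`W² = 1/12n + Σ (u_(i) − (2i−1)/2n)²`, asymptotic
p-value).  These p-values are calibrated when the tested model is fixed;
when the model has been fitted to the same data they are conservative, as
is generic for goodness-of-fit tests with estimated parameters.

## Stage 2 — spatial model

On-effort tracklines (off-effort fixes split a transect into separate
polylines) are cut into `n = max(1, round(L / 1 km))` equal segments, so
effort length is conserved exactly and no sliver segments destabilize the
GAM.  Each segment midpoint is annotated with raster covariates — depth,
slope, distance from coast (DFC), distance from the 200 m isobath (DF200),
and 8-day composite SST and CHL matched by segment date — by containing-cell
lookup with half-open cells (no interpolation, matching composite
semantics).  The per-segment response is the Horvitz–Thompson estimate
`n̂_j = Σ s_i/p_i` (individuals; clusters optional) with searched area
`A_j = 2 w l_j` as a log offset:

    E[n̂_j] = A_j exp(β₀ + Σ_k f_k(z_jk)),  n̂_j ~ Tweedie(q, φ) or NB(θ).

Smooths are P-splines: uniform cubic B-spline bases with second-order
difference penalties, `k = 10` per 1-D term; longitude/latitude always
enter as a single bivariate tensor-product smooth (`k = 25`, isotropic
Kronecker-sum penalty — both margins are in projected metres).  Each smooth
is centred (sum-to-zero) by reparameterization.  Smoothing parameters
minimize the REML score of the working Gaussian model at the converged
penalized-IRLS weights with dispersion profiled by the Pearson estimator
("performance iteration"); PIRLS uses step-halving on the penalized
deviance.  The Tweedie power is profiled over a grid in (1.1, 1.9) against
the series log-likelihood; NB θ is estimated by ML inside the fit loop.
Term p-values are approximate Wald tests of each smooth's coefficient block
against the Bayesian covariance `V_β = φ(XᵀWX + S_λ)⁻¹` on `edf` degrees of
freedom — adequate for backward selection, but not exact for penalized
fits.  Backward selection removes the single largest-p term above the
threshold (α = 0.05; 0.1 for the sparse striped-dolphin case), refits, and
repeats; the removal trail is returned so the path is auditable.  Model
variants (family, term sets) are compared by AIC, REML score and percent
deviance explained on identical responses.

Predictions are clamped to the fitted covariate range (cells beyond it are
flagged as extrapolation and reported, but still included in totals).

## Uncertainty

Total abundance over a prediction grid (4 km cells; edge cells clipped) is
`N̂ = Σ_c A_c exp(η_c)`, no renormalization.  Its GAM CV is delta-method:
`var(N̂) = aᵀ V_β a` with `a = Σ_c N̂_c x_c`.  Detection and GAM components
combine in quadrature, `CV² = CV_det² + CV_gam²` (independent: detection is
fitted to pooled data, the GAM per species), and the 95% interval is the
standard lognormal `[N̂/C, N̂·C]`, `C = exp(z₀.₉₇₅ √ln(1 + CV²))`.  These
two conventions jointly reproduce the published worked examples of this
survey type to printed precision.

## Synthetic surveys

The generator emulates the reference survey at desk scale so every stage
has a recovery test with no external data.  Defaults (chosen once, as the
study conditions):

* region 400 × 400 km; 4 km covariate rasters as band-limited Gaussian
  fields (white noise smoothed over 3 cells ≈ 12 km correlation length),
  mapped to plausible ranges (depth 0–4000 m, CHL lognormal > 0, SST
  ~21 ± 2.5 °C); SST/CHL as 8-day composites sharing a base field plus a
  small per-window perturbation;
* zigzag design with 30 km spacing → 13 legs, ~5,200 km of effort,
  mirroring the reference 5,333 km; one sea state per transect, drawn from
  a calm-weighted distribution on Beaufort 0–4;
* inhomogeneous Poisson cluster placement with log-intensity
  `−3.1 + 0.3·z(depth) + 0.4·z(log CHL)` (standardized fields; CHL on the
  log scale, as density–productivity relations are conventionally
  modelled, which keeps the log-intensity Gaussian instead of letting the
  lognormal tail of raw CHL concentrate the population into a few
  hotspots); cluster sizes zero-truncated Poisson (rate 4; fixed-size
  option for analytic checks); species labels assigned with the reference
  survey's composition (68:22:17:30 striped:common:bottlenose:unidentified);
* hazard-rate detection truth σ₀ = 200 m, b = 2.5, sea-state effect −0.10
  and cluster-size effect +0.15 on log σ, w = 500 m, yielding ~150
  detected clusters per survey.

Because the intensity is piecewise constant on the raster grid, placement
samples the Poisson process exactly cell by cell (count + uniform position
within cell), which is distributionally identical to thinning a homogeneous
envelope at `sup λ` but costs O(cells) however peaked the field is.

What the generator does **not** emulate: responsive movement, observer
fatigue, closing-mode path deviations, measurement error in distances and
covariates, species-specific habitat segregation, and temporal population
change.  Passing recovery tests therefore demonstrate the correctness of
the estimation chain under the stated model, not robustness to those field
realities.

## Problem sizes and numerical choices

Replicated studies in the test suite run at desk scale, chosen as the
package's own verification conditions: detection parameter recovery uses
n = 2000 distances over 20 seeds; GoF calibration 200 replicates of n = 137
(the reference cluster count); backward-selection operating characteristics
100 replicates of 300 segments with fixed Tweedie power; end-to-end
recovery 100 replicated surveys at the full reference effort with a
coarse Tweedie-power grid (1.3, 1.5, 1.7), reduced 1-D basis size (k = 6)
and an 8 km scoring grid.  End-to-end estimates recover truth within 20%
in at least 80% of replicates and the 95% CI covers truth at close to
nominal rate (both asserted by the test suite); single realizations can
still miss by more when the realized population concentrates between
transect lines — that is genuine survey variance, visible in the ratio's
spread, not estimator bias.

Other numerics: PIRLS converges on relative penalized-deviance change
1e−9 (cap 100 iterations); REML optimization is Nelder–Mead over log
smoothing parameters from the best of a shared coarse grid; μ is floored
at 1e−10; the linear predictor is clipped at ±30 before exponentiation;
detection likelihood evaluations floor at 1e10 outside the feasible
region.  Degenerate inputs (zero-length transects, all-missing rasters,
empty candidate lists, non-positive truncation) raise or are skipped with
logged counts as documented per function.

## Known limitations

* Term p-values for penalized smooths are first-order Wald approximations;
  selection near the threshold can differ from exact tests.
* The REML score is the working-model (PQL-type) approximation, not the
  exact Tweedie/NB restricted likelihood; REML values are comparable
  across models fitted by this engine but not directly against other
  software.
* Uncertainty in the Tweedie power / NB θ and in smoothing parameters is
  not propagated into `V_β`.
* Prediction-grid clamping treats covariates beyond the fitted range as
  boundary values; extrapolation is flagged, not modelled.
* No spatial autocorrelation beyond what the covariates induce; no
  per-cell confidence maps.
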