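# Methods

## Model

The outcome is a daily count `y_t` of deaths with expectation `μ_t` and a
quasi-Poisson variance `Var(y_t) = φ μ_t`, `φ ≥ 1` the (unknown) dispersion.
The mean model is log-linear in a confounder block and a pollutant block:

```
log μ_t = α + θ₁ ns(Temp14_t; 3) + θ₂ ns(RH_t; 3) + θ₃ ns(Press_t; 3)
        + θ₄ ns(t; df_time) + δ₁ DOW_t + δ₂ Holiday_t + pollutant term.
```

`Temp14` is the 14-day trailing moving average of mean temperature;
`RH`/`Press` enter same-day. `ns(·; df)` is a natural cubic spline basis
(linear beyond the boundary knots, knots at equally spaced quantiles).
The pollutant exposures are 3-day (lag 0–2) trailing moving averages; a
moving average is missing whenever any constituent day is missing, so a
single missing monitoring day removes `window` design rows.

Four pollutant terms define the four competing models:

* **I** `β x_m` for one pollutant at a time (three separate fits);
* **II** `β₁ x₁ + β₂ x₂ + β₃ x₃`;
* **III** Model II plus the raw pairwise products `x_a x_b`;
* **IV** a tensor-product smooth `te(x₁, x₂, x₃)`.

Confounder degrees of freedom are fixed inputs, not re-selected: df 3 per
meteorological variable, and 7 per year of data for the time spline (so 56
over eight years). "df per year" is the convention in daily-mortality
series — a fixed small total cannot absorb several annual cycles — but an
absolute total can be pinned via `df_time_total` instead.

## Tensor-product smooth

Each margin is a cubic regression spline basis: a clamped cubic B-spline
basis of dimension `d` (default 5, minimum 4 — a cubic B-spline basis does
not exist below dimension 4) with `d − 4` interior knots at quantiles of
the observed lagged exposure. The marginal roughness penalty is exact:
`S_ij = ∫ B_i'' B_j'' dx` over the observed range, computed by a 2-point
Gauss rule per knot interval, which is exact because cubic B-spline second
derivatives are piecewise linear. Its null space contains every affine
function.

The trivariate basis row at `(pm10, no2, so2)` is the Kronecker product of
the marginal rows in the layout `v[i, l, k] ↔ flat index (i·L + l)·K + k`
(PM10 slowest, SO2 middle, NO2 fastest). Each margin's penalty is expanded
to the full coefficient space by Kronecker products with identity matrices
on the other two margins; the objective penalizes exactly the three pure
second derivatives — mixed derivatives are unpenalized, so the joint null
space is the span of multilinear functions `{1, x, y, z, xy, xz, yz, xyz}`.

Because B-splines sum to one, the raw tensor basis contains the constant
and would be confounded with the intercept. Identifiability is restored by
a sum-to-zero constraint over the sample: with `c` the vector of tensor
column means, the design is reparameterized by an orthonormal basis `Z` of
the null space of `cᵀ` (so 125 → 124 columns at dimensions 5×5×5).
Contrasts `te(x_j) − te(x_i)` are invariant to this centering.

## Estimation

For fixed smoothing parameters `λ = (λ_PM10, λ_NO2, λ_SO2)` the
coefficients maximize the penalized quasi-log-likelihood, i.e. minimize
the Poisson deviance plus `Σ_m λ_m βᵀ S_m β` (the objective is read as
likelihood **minus** penalty — the only coherent sign). PIRLS iterates
weighted least squares on the working response `z = η + (y − μ)/μ` with
weights `W = diag(μ)`, solving `(XᵀWX + Σ λ_m S_m) β = XᵀWz` by Cholesky
factorization, with step-halving so the penalized deviance never
increases. Initialization `μ⁰ = y + 0.5` guards `log 0`; convergence is a
relative penalized-deviance change below 1e-8 (cap 200 iterations,
non-convergence raises with the iteration trace). The dispersion never
enters the mean fit.

Post-fit quantities at the converged weights:

* effective degrees of freedom `edf = tr[(XᵀWX + ΣλS)⁻¹ XᵀWX]`;
* Pearson dispersion `φ̂ = Σ (y − μ̂)²/μ̂ / (n − edf)`;
* coefficient covariance — default the frequentist sandwich
  `Σ̂ = φ̂ H⁻¹ (XᵀWX) H⁻¹` with `H = XᵀWX + ΣλS`; the Bayesian form
  `φ̂ H⁻¹` is always computed alongside and selectable via `cov_type`.
  The two coincide without penalty and differ under heavy smoothing; the
  sandwich is the default because the effect CIs are frequentist
  statements about fixed contrasts.

Smoothing parameters minimize `GCV(λ) = n·P(λ)/(n − edf)²` with `P` the
Pearson statistic — the scale-free criterion when `φ` is unknown — by
cyclic coordinate descent over a log-spaced grid (default 7 points per
decade on 1e-4…1e6, two cycles) with golden-section refinement between the
bracketing grid neighbours. Successive evaluations warm-start PIRLS from
the previous coefficients. A minimum on the grid boundary is recorded as a
warning in the fit log; with an exactly log-linear truth the optimum
genuinely sits at the upper boundary (the penalty null space contains the
truth), which is expected behaviour, not failure.

## Effect estimation

Every reported effect is a linear functional `cᵀβ̂` of the coefficients:

* Models I/II: `c` holds the exposure increments on the pollutant columns
  (Model I's "combined" effect sums three independent fits, with zero
  cross-fit covariance);
* Model III: increments plus the differences of the pairwise products
  between the two profiles;
* Model IV: the difference of centered tensor rows, nonzero only on the
  smooth columns — confounder columns cancel in any pure exposure
  contrast, so Σ̂ is restricted to the smooth block.

Then `RR = exp(cᵀβ̂)`, `se = √(cᵀΣ̂c)`, `CI = exp(cᵀβ̂ ± z₀.₉₇₅ se)` and
`ER = (RR − 1)·100 %`. The default contrast is the 25th → 75th percentile
of each lagged exposure (an IQR increase), computed from the days actually
retained in the model. Tensor contrasts refuse levels more than 10% of the
training range beyond the knots, since spline extrapolation is
uncontrolled. RR surfaces fix one pollutant at its 25th percentile and
grid the other two over their 1st–99th percentiles; exposure-response
curves fix two pollutants at the reference.

## Synthetic data generator

The generator emulates an eight-year series from a large city: 2,922 days,
baseline 66 deaths/day, pollutant means (74.9, 62.4, 41.0) μg/m³ for
(PM10, NO2, SO2) with log-scale SDs (0.50, 0.43, 0.65) chosen to match the
observed coefficients of variation, and Spearman correlation targets
(0.83, 0.60, 0.65) for (PM10–NO2, PM10–SO2, NO2–SO2).

Pollutants are exponentiated Gaussian latents — guaranteeing positivity
and right skew — plus a shared annual sinusoid (amplitude 0.25 on the log
scale) on each latent. Spearman targets are converted to latent Pearson
correlations by the exact Gaussian-copula relation `ρ = 2 sin(π ρ_s/6)`;
the deterministic seasonal component is budgeted *inside* the latent
covariance, so the configured correlations refer to the full series.
Weather is sinusoidal-plus-noise (temperature amplitude 6.5 °C around
22.5 °C; humidity clipped to [5, 99]%; pressure around 1007.4 hPa); the
holiday flag uses a fixed synthetic day-of-year calendar. The seasonal
phase is configurable and the generator makes no claim about which
half-year is the high-mortality season.

The true log-rate adds a mortality seasonality (amplitude 0.12), a linear
effect of the 14-day temperature average (−0.004/°C), and a configurable
pollutant surface — additive linear (default slopes 4e-4, 5e-4, 5e-4 per
μg/m³ of the 3-day moving average, i.e. roughly a 2% excess risk per raw
IQR each), linear with pairwise products, an arbitrary smooth callable, or
null. The non-intercept terms are centered before exponentiation so the
mean count stays at the configured baseline. Counts are Poisson at φ = 1
and negative binomial moment-matched to `Var = φμ` otherwise (quasi-
likelihood fixes only the mean–variance relation; the NB is the standard
simulable stand-in); the default φ is 1.5. The per-day true `μ_t` is
returned alongside the draws for oracle use, and warm-up days of the true
surface use partial-window means so the series is complete.

What the generator does **not** emulate: multi-site monitoring and spatial
averaging, realistic holiday calendars, long-term pollution trends,
cause-specific mortality, autocorrelated residual structure beyond the
shared seasonality, and measurement error in exposures. Passing recovery
tests therefore demonstrates the estimators' correctness under the model's
own assumptions, not robustness to every failure mode of real registry
data.

## Validation studies and problem sizes

The simulation studies fix their own scale as a design choice: recovery
and model-comparison runs use tensor dimensions (4, 4, 4) with a coarse
GCV grid (1 point per decade plus golden-section refinement, one cycle),
which reproduces the same selected smoothing regime as the default search
on these data at a fraction of the fits; single-fit checks (SE bootstrap,
GCV-vs-extremes) use the default (5, 5, 5). The parametric bootstrap for
the delta-method check samples the coefficient sampling distribution with
randomized quasi-Monte-Carlo normal draws, whose SD estimate at 200 draws
is far more accurate than plain Monte Carlo. The unpenalized comparison
fit uses λ = 0 exactly; the over-smoothed one λ = 1e9 per margin.

## Numerical choices and degenerate inputs

* Penalized-Hessian solves use Cholesky; rank deficiency raises an error
  naming the leading loadings of the null direction.
* Indicator columns with no occurrences among the retained days (e.g. a
  holiday-free sample) are dropped with a logged warning rather than left
  as all-zero columns.
* More than 10% of days dropped for missingness triggers a warning; zero
  complete rows is an error.
* The log-rate is clipped at ±30 inside PIRLS; the generator refuses true
  log-rates above 30, naming the offending day.
* All generators are deterministic given their seed; pipeline artifacts
  carry a configuration hash and seed and contain no timestamps, so reruns
  are byte-identical.

## Known limitations

* GCV is the only smoothness-selection criterion (no REML), and the λ
  search is coordinate-wise — adequate for three smoothing parameters but
  not meant for many.
* The tensor smooth penalizes pure second derivatives only; an analysis
  wanting penalized mixed derivatives needs a different penalty expansion.
* Confounder splines are unpenalized with fixed df; there is no automatic
  df selection.
* Quantile knots make the basis data-dependent: refitting on a different
  day subset moves the knots slightly. Serialized bases reload
  bit-identically, which is the supported route for out-of-sample
  evaluation.
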