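# tegam

Tensor-product quasi-Poisson generalized additive models for estimating the
**combined effect of several correlated air pollutants** on daily mortality.

## The problem

Daily city-level time series of death counts and pollutant concentrations
(here PM10, NO2 and SO2, in μg/m³) are the workhorse of short-term
air-pollution epidemiology. The pollutants are strongly correlated
(Spearman correlations of 0.6–0.85 are typical), so the usual approaches
are both unsatisfactory:

* three **single-pollutant models** overstate the joint burden — each fit
  absorbs part of the other pollutants' effects, and summing the three
  excess risks double-counts;
* a **joint linear model** suffers variance inflation and sign reversals
  under collinearity, and forces additivity on the log scale.

`tegam` implements a third route: the three exposures enter one penalized
**tensor-product smooth** `te(PM10, NO2, SO2)` inside a quasi-Poisson GAM,

```
log μ_t = α + θ₁ ns(Temp_t) + θ₂ ns(RH_t) + θ₃ ns(Press_t) + θ₄ ns(time)
        + δ₁ DOW_t + δ₂ Holiday_t + te(PM10_t, NO2_t, SO2_t),
Var(y_t) = φ μ_t,
```

where `ns(·)` are natural cubic splines (df 3 for weather, 7 per year for
time), exposures are 3-day (lag 0–2) moving averages, and temperature is a
14-day moving average. The tensor smooth is built from cubic regression
spline marginal bases combined by Kronecker products,

```
te(x₁, x₂, x₃) = Σᵢ Σₗ Σₖ v_ilk ϕᵢ(PM10) φₗ(SO2) ηₖ(NO2),
```

with one roughness penalty `λ_m ∫ (∂²f/∂x_m²)² dx` per margin. Coefficients
are estimated by penalized iteratively re-weighted least squares (PIRLS);
the three smoothing parameters are selected by generalized cross-validation
(GCV) on the Pearson statistic. Effects are reported as rate ratios

```
RR = exp(teᵀν̂),   se = √(teᵀ Σ̂ te),   ER = (RR − 1) × 100 %,
```

where `te` is the difference of tensor basis rows between two exposure
profiles (default: each pollutant's 25th → 75th percentile, an IQR
increase) and Σ̂ is the coefficient covariance. The package also fits the
three competing specifications — single-pollutant (Model I), joint linear
without (Model II) and with (Model III) pairwise interactions — with the
matching combined-effect estimators, so the four can be compared on the
same data.

Real mortality registry series are rarely shareable, so the package ships a
**synthetic-data generator** with the same statistical structure (correlated
seasonal log-normal-like pollutants via a Gaussian copula, confounded
overdispersed counts) and a *known* true log-rate surface, which is how the
estimators are validated: by parameter recovery, not by eyeballing.

## Worked example

```python
import numpy as np
import tegam as tg

sim = tg.SimulationConfig(n_days=2922, seed=1, dispersion=1.5)
data = tg.simulate_dataset(sim)                      # 8 years of daily data
built = tg.build_model(data, tg.ModelSpec(model="IV", tensor_dims=(4, 4, 4)))
lambdas, fit = tg.gcv_select(built.design, tg.GCVConfig(points_per_decade=1, cycles=1))
print(f"selected log10(lambda): {np.round(np.log10(lambdas), 2)}")
print(f"edf = {fit.edf:.1f}, dispersion = {fit.dispersion:.3f}")

ref = {p: built.quantile(p, 0.25) for p in tg.POLLUTANTS}
to = {p: built.quantile(p, 0.75) for p in tg.POLLUTANTS}
est = tg.rr_tensor(fit, built.smooth, ref, to)
lo, hi = est.er_ci
print(f"combined IQR-contrast ER = {est.er_percent:.2f}% (95% CI {lo:.2f} to {hi:.2f})")
```

prints

```
selected log10(lambda): [5.99 5.99 4.54]
edf = 89.0, dispersion = 1.532
combined IQR-contrast ER = 2.80% (95% CI 1.27 to 4.36)
```

The generator's true effect for this contrast is an ER of 3.53%, inside the
interval: moving all three pollutants from their 25th to their 75th
percentile raises the expected daily death count by an estimated 2.8%, the
GCV-selected fit uses ≈89 effective degrees of freedom, and the Pearson
dispersion estimate 1.53 recovers the generating overdispersion of 1.5.

The same analysis from the shell:

```bash
tegam simulate --seed 1 --n-days 2922 --out series.csv
tegam compare --input series.csv --seed 1 --output-dir out/
```

which writes `comparison_table.csv` (per-pollutant and combined ER with
95% CIs for Models I–IV), per-model fit logs, and the Model IV RR surfaces
and exposure-response curves as CSV grids. `tegam stratify` and
`tegam sensitivity` rerun the pipeline per stratum and per lag window.

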