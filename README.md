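# gamar

Poisson generalized additive models with autoregressive terms (GAMAR) for
daily count time series, built for environmental-epidemiology settings such
as temperature–mortality studies.

## Why

The workhorse models of time-series epidemiology — Poisson GLM/GAM with
natural-spline smoothers of weather and pollution covariates — assume the
daily counts are conditionally independent. Daily mortality and morbidity
series rarely are: the response itself is serially correlated. Ignoring
that autocorrelation leaves the point estimates roughly unbiased but makes
the reported standard errors far too small, so confidence intervals on
temperature effects cover the truth much less often than advertised, and
the Pearson residuals look overdispersed even when the counts are
conditionally Poisson.

GAMAR fixes this by adding observation-driven AR feedback on the link
scale. For counts `y_t` with covariate design row `X_t`,

    y_t | past ~ Poisson(mu_t)
    ln mu_t = eta_t = sum_i beta_i X_ti
              + sum_{j=1}^p c_j ( ln y*_{t-j} - sum_i beta_i X_{t-j,i} )

where `y*_t = max(y_t, tau)` with a small positive threshold `tau`
(default 0.5) so the logarithm is defined at zero counts. The design
columns are an intercept, natural cubic spline bases `ns(x, df)` of the
covariates (possibly lagged), linear columns, and factor indicators such
as day-of-week. Each AR term feeds back the link-scale discrepancy between
the observed count and the covariate part of the predictor at lag `j`, so
the `c_j` absorb the residual serial correlation that a plain GAM leaves
behind. Setting `p = 0` recovers the ordinary Poisson GAM.

Parameters `theta = (beta, c)` are estimated by maximum partial
likelihood — the product of Poisson conditionals given the past, taken
over `t = p+1..n` — using a modified Newton iteration
`theta <- theta + Gamma*^{-1} score`, where `Gamma*^{-1}` inverts the
observed information after flooring its eigenvalues at `delta = 0.01` to
keep the step matrix positive definite, with step-halving to guarantee
monotone ascent. Wald intervals come from `Gamma*^{-1}` at the optimum;
AIC is `-2 logPL + 2(m+p)`; the Pearson dispersion
`phi = sum z_t^2 / (n - m - p)` and the residual ACF/PACF diagnose
leftover autocorrelation and suggest the AR order.

## Worked example

Simulate a 4-year daily series from the AR(3) spline model (true
coefficients: intercept 5.02, spline loadings −0.35, −0.36, −0.38, −0.33,
−0.15, AR coefficients 0.5, 0.25, 0.12) over a synthetic seasonal
temperature series, then fit GAMAR(3):

```python
from gamar import (ModelSpec, SmoothTerm, SyntheticSeriesConfig,
                   fit_gamar, simulate_gamar, spline_study_truth,
                   synth_temperature, whiteness_report)

truth = spline_study_truth()
x = synth_temperature(SyntheticSeriesConfig(n_days=truth.n_days, seed=1))
data = simulate_gamar(x, truth, seed=2)

fit = fit_gamar(ModelSpec([SmoothTerm("temp", 5)], ar_order=3), data)
print(fit.params_frame().round(4).to_string(index=False))
print(f"loglik={fit.loglik:.2f}  aic={fit.aic:.2f}  phi_hat={fit.phi_hat:.4f}")
```

```
        term  estimate     se        z     p
 (intercept)    4.9881 0.0298 167.6469 0.000
ns(temp,5).1   -0.3186 0.0221 -14.4251 0.000
ns(temp,5).2   -0.3131 0.0296 -10.5830 0.000
ns(temp,5).3   -0.3609 0.0270 -13.3889 0.000
ns(temp,5).4   -0.2459 0.0515  -4.7787 0.000
ns(temp,5).5   -0.0891 0.0350  -2.5438 0.011
         AR1    0.4580 0.0256  17.8979 0.000
         AR2    0.2761 0.0273  10.1202 0.000
         AR3    0.1430 0.0257   5.5687 0.000
loglik=-5516.50  aic=11051.00  phi_hat=1.0265
```

Every estimate sits within two standard errors of its true value and the
dispersion is ≈ 1. The plain GAM (`ar_order=0`) on the same data gives
`phi_hat = 2.94` — the classic overdispersion signature of unmodelled
autocorrelation — and its residual PACF is flagged exactly at lags 1–3
(`whiteness_report(fit.residuals, 20).suggested_order == 3`), pointing at
the AR(3) structure; the GAMAR(3) residuals are close to white noise.

The same workflow is available from the shell:

```sh
gamar simulate --model spline --seed 1 --out sim.csv
gamar fit sim.csv --config model.yaml --out fitdir/
gamar diagnose fitdir/fitted.csv --out correlogram.csv
gamar replicate --model spline --n-reps 1000 --seed 1 --out study1/
gamar select sim.csv --config grid.yaml --out chosen.json
```

where `model.yaml` uses the compact term syntax

```yaml
count: y
index: t
terms: [ "ns(temp, df=5)" ]
ar_order: 3
tau: 0.5
```

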