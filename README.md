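# fdamort

Functional regression models for weather-related mortality time series.

Environmental epidemiology usually relates daily death counts to scalar
temperature summaries (daily mean, minimum, maximum) through lagged GAMs or
distributed lag non-linear models (DLNMs). Those models cannot see *within-day*
temperature structure, nor how the temperature–mortality relationship shifts
across the season. `fdamort` treats temperature and mortality as **curves**
(functional data) and fits the two functional regression models that address
these gaps, alongside the classical comparators and a blocked cross-validation
harness to benchmark them all on the count scale.

## Models

**Scalar-response functional linear model (SFLM).** The log daily
cardiovascular death count is driven by the whole previous-day temperature
curve:

```
ln(y_i) = s(i) + β₀ + ∫₀²⁴ x_{i−1}(s) β₁(s) ds + ε_i
```

`s(i)` is a long-term-trend natural spline (one knot every three months of
observed days), and β₁(s) is a functional coefficient on [0, 24] hours
expanded in cubic B-splines, estimated by penalized least squares with a
second-derivative roughness penalty (λ by GCV). Pointwise 95% confidence
bands for β₁ come from a wild (Rademacher) residual bootstrap, 500 replicates
by default.

**Historical fully functional linear model (FFLM).** The annual log-mortality
curve responds to the same year's temperature over the preceding 60 days:

```
ln(y_i(t)) = s(i) + β₀(t) + ∫_{t−60}^{t} x_i(s) β₁(s,t) ds + ε_i(t)
```

β₁(s,t) is a tensor-product B-spline surface with *exact* triangular band
support (zero unless t−60 ≤ s ≤ t), fitted on a daily grid with anisotropic
second-derivative penalties. Temperature curves are centred at the across-year
mean curve, so the surface acts on anomalies and β₀(t) absorbs the seasonal
mean cycle.

**Comparators.** Lag-1 GAMs in each scalar temperature summary (min / mean /
max / diurnal range) and a 60-day DLNM cross-basis with B-spline knots at the
10th/75th/90th temperature percentiles and log-spaced lag knots, optionally
interacted with one day-of-year harmonic. All models share the same
Gaussian-on-log-counts estimation and are compared by leave-one-year-out
blocked cross-validated RMSE on the count scale.

**Synthetic data.** Because administrative mortality data cannot be shipped,
`fdamort.synthetic` generates seeded hourly/daily temperature series (seasonal
and diurnal sinusoids plus AR(1) noise) and Poisson death counts whose
log-rate contains a known functional effect, at the scale of a large
metropolitan area (≈17 deaths/day). The generator shares the estimators'
integral machinery, so every stage of the pipeline is testable against a known
truth.

## Worked example

```python
import numpy as np
from fdamort import (Scenario, make_sflm_dataset, fit_sflm,
                     wild_bootstrap_band, SFLMConfig)

ds = make_sflm_dataset(Scenario(seed=1, mode="sflm", n_years=5))
print("days:", len(ds.counts), " mean deaths/day:", round(ds.counts.mean(), 1))

cfg = SFLMConfig(seed=1)
fit = fit_sflm(ds.counts, ds.exposures, cfg)
print("chosen smoothing parameter: %.3g" % fit.chosen_smoothing)

g = np.linspace(0, 24, 100)
corr = np.corrcoef(fit.beta1_on_grid(g), ds.true_beta1.evaluate(g)[0])[0, 1]
print("corr(beta1_hat, beta1_true): %.3f" % corr)

band = wild_bootstrap_band(fit, cfg)
k = np.argmax(band.point_estimate)
print("beta1 peak at s = %.1f h, 95%% band [%.4f, %.4f]"
      % (band.grid[k], band.lower_95[k], band.upper_95[k]))
```

prints

```
days: 460  mean deaths/day: 20.1
chosen smoothing parameter: 7.55e+03
corr(beta1_hat, beta1_true): 0.996
beta1 peak at s = 5.8 h, 95% band [0.0393, 0.0473]
```

Five simulated summers (460 days, matching the June–August 2007–2011 layout)
suffice to recover the generating intraday coefficient almost exactly
(correlation 0.996); the band at the morning peak excludes zero, i.e. warm
mornings on the previous day raise the day's expected mortality.

The same workflow is available from the shell:

```bash
fdamort simulate --mode sflm --seed 1 --out work/
fdamort fit-sflm --workdir work/ --seed 1
fdamort crossval --workdir work/
fdamort report  --workdir work/
```

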