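# Methods

## Functional data construction

Discrete measurements are turned into curves by unpenalized least-squares
spline smoothing. Bases are cubic B-splines (order 4) with equally spaced
interior knots; the knot count can be selected by point-level leave-one-out
cross-validation (`select_knots_loocv`), computed in closed form through the
hat-matrix identity e_i/(1−h_ii) and summed over curves. Ties resolve toward
fewer knots. Cubic order is a modelling choice: the smoothness of daily
temperature traces and annual mortality rates is well represented by C²
curves, and the second-derivative roughness penalties used downstream require
order > 2.

Default bases:

* exposure curves on [0, 24] h: 8 interior knots (dimension 12), fitted to 24
  hourly readings;
* annual temperature on [0, 365] d: 8 interior knots (dimension 12);
* annual mortality response: 16 interior knots (dimension 20, ~one knot every
  three weeks). The response basis is finer than the temperature basis
  because the historical integral of week-scale temperature anomalies induces
  sub-monthly variation in the log-rate; a 12-dimensional response basis
  smooths away part of that signal, while dimension 20 retains it and still
  treats day-to-day Poisson noise as noise.

Daily mortality counts become response curves in two steps: smooth the counts
into a rate curve, clip the evaluated rate at 0.1 deaths/day, take logs, and
project back onto the basis (`log_rate_curves`). The clip guards the log for
hypothetical near-zero stretches; at a mean of ~17 deaths/day it is inactive
in practice.

All integrals in the regressions are computed exactly for splines:
Gram/cross-Gram/penalty matrices use Gauss–Legendre quadrature per knot span
with enough nodes for the product's polynomial degree, so quadrature is never
a tolerance source. The FFLM's windowed historical integrals use cumulative
composite Simpson on a quarter-day grid (h⁴ accuracy, ≲1e−8 relative), with
window endpoints required to land on even grid indices.

## Scalar-response model (SFLM)

Design: intercept + long-term-trend natural spline + functional columns.
The functional columns are the exposure coefficient rows multiplied by the
cross-Gram between the exposure basis and the coefficient basis — an exact
implementation of ∫ x_{i−1}(s) b_j(s) ds. The response is ln(max(y, 0.5)):
a Gaussian model on log counts keeps all seven models on one estimation
footing for the RMSE comparison, and the 0.5 floor handles the rare zero
count without switching to a Poisson likelihood.

β₁ carries a second-derivative penalty; λ is chosen by GCV over a 25-point
logarithmic grid scaled by tr(ZᵀZ)/tr(P), making the grid scale-free.
Identifiability: the trend block is reparameterized to exclude constants
(null space of the column-mean functional), so the intercept is unique.

The trend's knots are placed every 91 *observed* days, mapped to calendar
dates. Placing them by observed-day rank rather than raw calendar spacing
keeps every spline column supported when the data are concatenated summer
seasons with nine-month gaps. Two further trend safeguards matter only under
cross-validation refits: a tiny fixed roughness penalty (1e−6 relative) pins
trend coefficients whose data support is emptied by holding out a year to the
smooth interpolation of their neighbours, and prediction holds the trend at
its boundary value beyond the fitted data range — extrapolating a
seasonal-resolution spline's end slope across a held-out year is meaningless.
Prediction still refuses dates beyond the configured calendar range plus one
knot spacing.

### Wild bootstrap

Replicates perturb fitted values with sign-flipped residuals (Rademacher
multipliers, one per day), preserving heteroscedasticity, and refit with the
*same* λ; bands are pointwise 2.5/97.5 percentiles of β̂₁ over replicates.
The default 500 replicates is the shipped setting; the implementation
vectorizes all replicates through one precomputed solver, so coverage
simulations are cheap. Percentile bands of a penalized estimator inherit its
smoothing bias, which is why measured coverage sits a few points below the
nominal 95% (≈90% on the reference scenario) — within the accepted range but
a known limitation of same-λ residual bootstraps.

## Historical function-on-function model (FFLM)

The response curves are discretized on the 365 day-centre grid; the design
stacks a year-level natural-spline trend (≤4 df, constants removed, knot
count capped below the number of distinct fitted years so the trend can
never interpolate the year means exactly), the
functional intercept β₀(t) on the t-basis, and one column per *masked*
tensor-product coefficient. A tensor pair (j,k) is masked in when the support
rectangle of b_j(s)·b_k(t) intersects the lag band {t−60 ≤ s ≤ t}; masked-out
coefficients are structurally zero and surface evaluation multiplies by the
band indicator, so off-band values are exactly zero, not merely small.

Anisotropic penalties λ_s (P_s ⊗ G_t) + λ_t (G_s ⊗ P_t) act on the masked
coefficients; (λ_s, λ_t) are chosen by GCV over a 7×7 logarithmic grid. The
GCV denominator uses the *effective* observation count n_years × dim(response
basis) rather than the raw grid size: grid values of a smoothed response are
strongly correlated, and treating them as independent information makes GCV
undersmooth badly (verified on noise-free recovery runs).

Identifiability: temperature anomalies (centred at the across-year mean
curve) enter the integral, so β₀(t) absorbs the seasonal mean temperature
signal. For t < 60 the window truncates at 0 rather than importing the
previous year's data. Predictions are returned as dense daily grids on the
count scale (exponentiation leaves the spline space); `discretize()` yields
the 365-per-year series used for scoring. Model residuals are likewise kept
as dense grid values, so fitted + residual reproduces the response exactly on
the grid — a finite spline basis could not represent the residual exactly.

## Classical comparators

All baselines regress ln(max(y, 0.5)) on the same trend construction plus
their exposure term, by penalized least squares with GCV, so the RMSE
comparison isolates how exposure is represented:

* **Lag-1 GAMs**: a 10-function cubic B-spline in one previous-day summary
  (min/mean/max/diurnal range) with a second-derivative penalty; the smooth
  block is reparameterized to exclude constants.
* **DLNM**: a 60-day cross-basis — row i is Σ_lag B_temp(x_{i−lag}) ⊗
  B_lag(lag) — with temperature knots at the 10th/75th/90th percentiles and
  lag knots equally spaced on the log(lag+1) scale (so lag 0 is included).
  Basis dimensions default to 7 (temperature) × 6 (lag). Because both
  marginal bases are partitions of unity, whole coefficient patterns map to
  constant design columns; the penalized block is reduced to full column rank
  by SVD of the column-centred design before a ridge penalty is applied.
  Rows without a full 60-day history are excluded from the likelihood. The
  day-of-year variant additionally modulates the cross-basis columns by one
  sine/cosine annual harmonic.

## Blocked cross-validation

Folds are calendar years. Each fold refits on the remaining years (the trend
knot layout is fixed from the full date range so held-out years remain inside
the spline's calendar span) and predicts the held-out year on the count
scale; squared errors are pooled across folds before the square root, giving
one RMSE per model, with per-fold values reported for diagnostics. In the
annual application the first 60 days of the record (incomplete DLNM history)
are excluded from scoring for *all* models so every model is scored on
identical days. A fold whose fit fails is reported and invalidates the
overall RMSE rather than being silently dropped.

## Synthetic scenarios

Temperature: seasonal mean 7 °C with amplitude 16 °C peaking in mid-July
(day 197); the hourly mode adds a 4 °C diurnal sinusoid peaking mid-afternoon
and AR(1) noise per hour, the daily mode AR(1) noise per day (coefficient
0.7, innovation SD 1.5 °C). Counts are Poisson with log-rate = ln 17 + slow
trend + functional term (optionally gamma-mixed for overdispersion); a
log-rate above 10 aborts with diagnostics. The generator computes its
functional terms with the same cross-Gram / historical-integral routines the
estimators use, so generator and estimator agree on the integral operator to
machine precision — parameter-recovery failures therefore indicate estimation
problems, not disagreements about the estimand.

Reference effects: the intraday coefficient β₁(s) = sin(2πs/24)/24 (zero
daily-mean effect, so scalar summaries are genuinely handicapped); the annual
surface is strictly negative on the band (cold raises mortality), strongest
in fall and spring and weakest in mid-winter and mid-summer, with a lag
profile peaking ~10 days back. Its amplitude (4e−3) is calibrated so the
functional term contributes a count-scale signal of roughly one death per
day — the magnitude that separates the published cross-validated RMSEs of the
annual models. The sflm-mode functional term is centred across days so the
baseline keeps its meaning as the marginal mortality scale; the offset is
absorbed by the model intercept and does not change the estimand.

What the generator does *not* emulate: spatial structure, humidity/pollution
covariates, missing-data patterns, reporting artefacts, demographic drift,
or harvesting dynamics. Passing recovery tests therefore show that the
estimators work when their model is true at realistic noise levels — not that
real mortality data satisfy these models.

## Problem sizes and known limitations

Recovery and coverage checks run at the study's own scale (460 summer days;
31 years of 365 days); the coverage simulation uses 200 simulations × 200
bootstrap replicates and the model-ordering check 10 seeds, sizes at which
the Monte Carlo error is a small fraction of the margins being tested.

Limitations: estimation is Gaussian on log counts rather than a count
likelihood; bands are pointwise, not simultaneous, and slightly undercover
due to smoothing bias; the DLNM implements only what the RMSE comparison
needs (no relative-risk surfaces or centring conventions of the published
software); the synthetic comparison's RMSE gaps between functional and
classical models are wider than those reported on real data, because the
synthetic effects are exactly functional by construction.
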