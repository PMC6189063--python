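"""Historical fully functional linear model: band support, fit, prediction."""

import numpy as np
import pytest

from fdamort.basis import FunctionalSample, Interval, make_basis
from fdamort.fflm import (
    FFLMConfig,
    HistoricalSurface,
    band_mask,
    fit_fflm,
    historical_integrals,
    predict_fflm,
    surface_heatmap_table,
)
from fdamort.synthetic import ANNUAL_BASIS


def _grid():
    return np.arange(365.0) + 0.5


def _band(grid):
    S, T = np.meshgrid(grid, grid, indexing="ij")
    return (S <= T) & (S >= T - 60.0)


# ---------------------------------------------------------------------------
# Triangular support
# ---------------------------------------------------------------------------

def test_surface_is_exactly_zero_off_the_band(annual_fit):
    surf = annual_fit.beta1
    # s > t: exposure after the response day
    assert surf.evaluate([100.0], [50.0])[0, 0] == 0.0
    # s < t - 60: exposure older than the maximum lag
    assert surf.evaluate([10.0], [200.0])[0, 0] == 0.0
    grid = _grid()
    vals = surf.evaluate(grid, grid)
    assert np.all(vals[~_band(grid)] == 0.0)


def test_masked_out_tensor_coefficients_are_zero(annual_fit):
    surf = annual_fit.beta1
    assert np.all(surf.coefficients[~surf.support_mask] == 0.0)


def test_band_mask_keeps_only_pairs_touching_the_band():
    s_b = make_basis(Interval(0, 365), 8, order=4)
    t_b = make_basis(Interval(0, 365), 8, order=4)
    mask = band_mask(s_b, t_b, 60.0)
    for j in range(s_b.dimension):
        s_lo, s_hi = s_b.support(j)
        for k in range(t_b.dimension):
            t_lo, t_hi = t_b.support(k)
            assert mask[j, k] == ((s_lo < t_hi) and (s_hi > t_lo - 60.0))


# ---------------------------------------------------------------------------
# Historical integral
# ---------------------------------------------------------------------------

def test_historical_integral_matches_riemann_oracle(annual_data):
    temp = annual_data.temperature_sample
    s_basis = ANNUAL_BASIS
    t_pts = np.array([30.5, 100.5, 250.5, 364.5])
    I = historical_integrals(temp, s_basis, t_pts, 60.0)
    for r, t in enumerate(t_pts):
        lo = max(0.0, t - 60.0)
        g = np.linspace(lo, t, 20_001)
        w = np.full(g.size, g[1] - g[0])
        w[0] = w[-1] = 0.5 * (g[1] - g[0])
        X = temp.evaluate(g)[:3]
        B = s_basis.design_matrix(g)
        oracle = (X * w[None, :]) @ B
        assert np.abs(I[:3, :, r] - oracle).max() < 1e-6 * max(
            1.0, np.abs(oracle).max()
        )


def test_historical_integral_requires_aligned_grid(annual_data):
    with pytest.raises(ValueError, match="fine quadrature grid"):
        historical_integrals(
            annual_data.temperature_sample, ANNUAL_BASIS, np.array([10.1]), 60.0
        )


# ---------------------------------------------------------------------------
# Fit and recovery
# ---------------------------------------------------------------------------

def test_fitted_plus_residuals_reproduce_response_on_grid(annual_fit):
    recon = annual_fit.fitted_grid + annual_fit.residual_grid
    assert np.abs(recon - annual_fit.response_grid).max() < 1e-8


def test_surface_recovery_at_study_scale(annual_data, annual_fit):
    """31 years, known negative season-varying surface: in-band corr > 0.9."""
    grid = _grid()
    est = annual_fit.beta1.evaluate(grid, grid)
    tru = annual_data.true_surface.evaluate(grid, grid)
    band = _band(grid)
    assert np.corrcoef(est[band], tru[band])[0, 1] > 0.9


def test_null_surface_estimate_is_small(annual_data):
    from fdamort.fflm import default_mortality_basis, log_rate_curves
    from fdamort.synthetic import Scenario, default_fflm_surface, make_fflm_dataset

    null_surface = HistoricalSurface(
        ANNUAL_BASIS, ANNUAL_BASIS, np.zeros((12, 12)), 60.0
    )
    sc = Scenario(seed=77, mode="fflm", n_years=31, true_beta1=null_surface)
    ds = make_fflm_dataset(sc)
    mort = log_rate_curves(ds.counts_by_year, default_mortality_basis())
    fit_null = fit_fflm(mort, ds.temperature_sample)

    sc_eff = Scenario(seed=77, mode="fflm", n_years=31)
    ds_eff = make_fflm_dataset(sc_eff)
    mort_eff = log_rate_curves(ds_eff.counts_by_year, default_mortality_basis())
    fit_eff = fit_fflm(mort_eff, ds_eff.temperature_sample)

    grid = np.linspace(0.5, 364.5, 60)
    band = (
        np.meshgrid(grid, grid, indexing="ij")[0]
        <= np.meshgrid(grid, grid, indexing="ij")[1]
    )
    norm_null = np.sqrt(np.mean(fit_null.beta1.evaluate(grid, grid) ** 2))
    norm_eff = np.sqrt(np.mean(fit_eff.beta1.evaluate(grid, grid) ** 2))
    assert norm_null < 0.2 * norm_eff


def test_rejects_invalid_lag_and_mismatched_curves(annual_data):
    temp = annual_data.temperature_sample
    mort = FunctionalSample(temp.basis, temp.coefficients)  # same shape stand-in
    with pytest.raises(ValueError, match="max_lag"):
        fit_fflm(mort, temp, max_lag=0.0)
    short = FunctionalSample(temp.basis, temp.coefficients[:-2])
    with pytest.raises(ValueError, match="curves"):
        fit_fflm(short, temp)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def test_training_prediction_reproduces_exp_fitted(annual_data, annual_fit):
    pred = predict_fflm(
        annual_fit, annual_data.temperature_sample, annual_fit.year_indices
    )
    assert np.abs(pred.values - np.exp(annual_fit.fitted_grid)).max() < 1e-8


def test_uniform_temperature_shift_acts_through_band_integral(annual_data, annual_fit):
    """+1 degC everywhere changes log-prediction at t by the band integral of
    beta1(., t)."""
    temp = annual_data.temperature_sample
    one = np.ones_like(temp.coefficients[:1])  # partition of unity: curve == 1
    shifted = FunctionalSample(temp.basis, temp.coefficients[:1] + one)
    base = FunctionalSample(temp.basis, temp.coefficients[:1])
    p1 = predict_fflm(annual_fit, base, [1])
    p2 = predict_fflm(annual_fit, shifted, [1])
    delta = np.log(p2.values[0]) - np.log(p1.values[0])
    ones_curve = FunctionalSample(temp.basis, one)
    I = historical_integrals(ones_curve, annual_fit.config.s_basis, annual_fit.t_grid)
    Bt = annual_fit.config.t_basis.design_matrix(annual_fit.t_grid)
    expected = np.einsum(
        "jr,jk,rk->r", I[0], annual_fit.beta1.coefficients, Bt
    )
    assert np.abs(delta - expected).max() < 1e-8


def test_discretized_predictions_are_daily_and_positive(annual_data, annual_fit):
    pred = predict_fflm(
        annual_fit, annual_data.temperature_sample, annual_fit.year_indices
    )
    series = pred.discretize()
    assert series.size == 31 * 365
    assert np.all(series > 0)


def test_prediction_rejects_far_year_extrapolation(annual_data, annual_fit):
    one = FunctionalSample(
        annual_data.temperature_sample.basis,
        annual_data.temperature_sample.coefficients[:1],
    )
    with pytest.raises(ValueError, match="year index"):
        predict_fflm(annual_fit, one, [40])


# ---------------------------------------------------------------------------
# Heatmap table and smoothing path
# ---------------------------------------------------------------------------

def test_heatmap_table_shape_and_band_zeros(annual_fit):
    s_g = np.linspace(0.5, 364.5, 41)
    t_g = np.linspace(0.5, 364.5, 37)
    table = surface_heatmap_table(annual_fit, s_g, t_g)
    assert len(table) == 41 * 37
    off = (table.s > table.t) | (table.s < table.t - 60.0)
    assert np.all(table.value[off] == 0.0)


def test_heatmap_sign_pattern_matches_truth(annual_data, annual_fit):
    s_g = np.linspace(0.5, 364.5, 80)
    table = surface_heatmap_table(annual_fit, s_g, s_g)
    tru = annual_data.true_surface.evaluate(s_g, s_g).ravel()
    in_band = (table.s <= table.t) & (table.s >= table.t - 60.0)
    agree = np.sign(table.value[in_band]) == np.sign(tru[in_band.to_numpy()])
    assert agree.mean() >= 0.85


def test_inband_roughness_decreases_along_lambda_path(annual_data):
    from fdamort.fflm import default_mortality_basis, log_rate_curves
    from fdamort.basis import gram_matrix, penalty

    mort = log_rate_curves(annual_data.counts_by_year, default_mortality_basis())
    cfg0 = FFLMConfig()
    Ps = penalty(cfg0.s_basis, 2).matrix
    Pt = penalty(cfg0.t_basis, 2).matrix
    Gs, Gt = gram_matrix(cfg0.s_basis), gram_matrix(cfg0.t_basis)
    rough = []
    for lam in (1e1, 1e3, 1e5, 1e7):
        fit = fit_fflm(
            mort,
            annual_data.temperature_sample,
            config=FFLMConfig(smoothing_parameters=(lam, lam)),
        )
        C = fit.beta1.coefficients
        r = np.trace(C.T @ Ps @ C @ Gt) + np.trace(C.T @ Gs @ C @ Pt)
        rough.append(r)
    assert all(a >= b - 1e-12 for a, b in zip(rough, rough[1:]))
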