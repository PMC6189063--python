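"""Historical fully functional linear model (FFLM).

The annual log-mortality curve of year i is regressed on a smooth year trend,
a functional intercept beta0(t) and the same year's temperature curve acting
through a coefficient surface beta1(s, t) restricted to the preceding 60 days:

    ln(y_i(t)) = s(i) + beta0(t) + integral_{t-60}^{t} x_i(s) beta1(s, t) ds
                 + eps_i(t),     t in [0, 365]

beta1 is expanded in a tensor product of B-spline bases in s and t; tensor
coefficients whose support cannot touch the lag band {t - L <= s <= t} are
structurally zero, and the evaluated surface is exactly zero off the band.
Estimation is penalized least squares on a daily grid with anisotropic
second-derivative penalties in s and t, smoothing parameters by GCV.

Identifiability: each year's temperature curve is centred at the across-year
mean curve before entering the integral, so the surface acts on temperature
anomalies and the seasonal mean temperature signal is absorbed by beta0(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .basis import (
    BasisSystem,
    FunctionalSample,
    Interval,
    gram_matrix,
    make_basis,
    natural_spline_design,
    drop_constant_direction,
    penalty,
)

__all__ = [
    "FFLMConfig",
    "default_mortality_basis",
    "FFLMFit",
    "HistoricalSurface",
    "FFLMPrediction",
    "fit_fflm",
    "predict_fflm",
    "surface_heatmap_table",
    "historical_integrals",
    "band_mask",
    "log_rate_curves",
]

YEAR_DOMAIN = Interval(0.0, 365.0)
DEFAULT_MAX_LAG = 60.0
#: smoothed daily rates are clipped here before logging
RATE_FLOOR = 0.1
#: quarter-day step of the fine quadrature grid for the historical integrals;
#: divides both the day length and the half-day offsets of the fit grid
FINE_STEP = 0.25


def _default_year_basis() -> BasisSystem:
    return make_basis(YEAR_DOMAIN, 8, order=4)  # dimension 12


def default_mortality_basis() -> BasisSystem:
    """Response-smoothing basis: one knot every ~3 weeks (dimension 20).

    Fine enough to retain the sub-monthly rate variation the historical
    integral induces, coarse enough to treat day-to-day Poisson noise as
    noise.
    """
    return make_basis(YEAR_DOMAIN, 16, order=4)


@dataclass
class FFLMConfig:
    s_basis: BasisSystem = field(default_factory=_default_year_basis)
    t_basis: BasisSystem = field(default_factory=_default_year_basis)
    trend_dimension: int = 4  # effective df of the year trend (natural spline)
    lambda_grid: Sequence[float] = tuple(np.logspace(-4.0, 4.0, 7))
    smoothing_parameters: tuple[float, float] | None = None  # (lam_s, lam_t) or GCV
    n_t_grid: int = 365


@dataclass
class HistoricalSurface:
    """Coefficient surface beta1(s,t) with triangular lag-band support."""

    s_basis: BasisSystem
    t_basis: BasisSystem
    coefficients: np.ndarray  # (dim_s, dim_t); off-mask entries exactly 0
    max_lag: float = DEFAULT_MAX_LAG
    support_mask: np.ndarray = None  # boolean (dim_s, dim_t)

    def __post_init__(self) -> None:
        C = np.asarray(self.coefficients, dtype=float)
        if C.shape != (self.s_basis.dimension, self.t_basis.dimension):
            raise ValueError(
                f"coefficient table shape {C.shape} does not match basis "
                f"dimensions ({self.s_basis.dimension}, {self.t_basis.dimension})"
            )
        if self.support_mask is None:
            self.support_mask = band_mask(self.s_basis, self.t_basis, self.max_lag)
        C = np.where(self.support_mask, C, 0.0)
        self.coefficients = C

    def evaluate(self, s_grid, t_grid) -> np.ndarray:
        """Surface values on the grid; exactly 0 off the band {t-L <= s <= t}."""
        s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
        t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
        Bs = self.s_basis.design_matrix(s_grid)
        Bt = self.t_basis.design_matrix(t_grid)
        vals = Bs @ self.coefficients @ Bt.T  # (len(s), len(t))
        S, T = np.meshgrid(s_grid, t_grid, indexing="ij")
        in_band = (S <= T) & (S >= T - self.max_lag)
        return np.where(in_band, vals, 0.0)


@dataclass
class FFLMFit:
    trend_coefs: np.ndarray
    beta0: FunctionalSample  # single curve on t_basis
    beta1: HistoricalSurface
    residual_grid: np.ndarray  # (n_years, n_t): response - fitted on the grid
    response_grid: np.ndarray
    fitted_grid: np.ndarray
    t_grid: np.ndarray
    chosen_smoothing: tuple[float, float]
    config: FFLMConfig
    year_indices: np.ndarray
    temp_mean_coefs: np.ndarray  # centring curve (on the temperature basis)
    temp_basis: BasisSystem
    _trend_knots: np.ndarray = None
    _trend_Z: np.ndarray = None
    _mask_pairs: np.ndarray = None  # (n_masked, 2) [j, k] index pairs


@dataclass
class FFLMPrediction:
    """Predicted mortality curves on the fit grid, count scale."""

    values: np.ndarray  # (n_years, n_t)
    t_grid: np.ndarray
    year_indices: np.ndarray

    def discretize(self) -> np.ndarray:
        """Daily predicted series, one value per day, concatenated by year."""
        return self.values.reshape(-1)


# ---------------------------------------------------------------------------
# Band support and the historical integral
# ---------------------------------------------------------------------------

def band_mask(
    s_basis: BasisSystem, t_basis: BasisSystem, max_lag: float
) -> np.ndarray:
    """Tensor pairs (j, k) whose supports can intersect {t-L <= s <= t}."""
    ds, dt = s_basis.dimension, t_basis.dimension
    mask = np.zeros((ds, dt), dtype=bool)
    for j in range(ds):
        s_lo, s_hi = s_basis.support(j)
        for k in range(dt):
            t_lo, t_hi = t_basis.support(k)
            mask[j, k] = (s_lo < t_hi) and (s_hi > t_lo - max_lag)
    return mask


def historical_integrals(
    temperature: FunctionalSample,
    s_basis: BasisSystem,
    t_grid: np.ndarray,
    max_lag: float = DEFAULT_MAX_LAG,
    fine_step: float = FINE_STEP,
) -> np.ndarray:
    """I[i, j, r] = integral over [max(0, t_r - L), t_r] of x_i(s) b_j(s) ds.

    Computed by cumulative composite Simpson on a fine grid whose step divides
    the window endpoints, shared by the estimator and the synthetic generator
    so both sides agree on the integral operator exactly.
    """
    dom = temperature.basis.domain
    n_fine = int(round(dom.span / fine_step))
    if n_fine % 2:
        raise ValueError("fine_step must divide the domain into an even count")
    s_fine = dom.lower + fine_step * np.arange(n_fine + 1)
    Xf = temperature.evaluate(s_fine)  # (n, m)
    Bs = s_basis.design_matrix(s_fine)  # (m, ds)
    prod = Xf[:, None, :] * Bs.T[None, :, :]  # (n, ds, m)
    # cumulative composite Simpson at even fine-grid indices (h^4 accuracy,
    # so the quarter-day step already beats the 1e-6 oracle tolerance)
    seg = (fine_step / 3.0) * (
        prod[..., 0:-2:2] + 4.0 * prod[..., 1::2] + prod[..., 2::2]
    )
    C = np.concatenate(
        [np.zeros(prod.shape[:-1] + (1,)), np.cumsum(seg, axis=-1)], axis=-1
    )  # value k = integral up to even index 2k
    t_grid = np.asarray(t_grid, dtype=float)
    lo_vals = np.clip(t_grid - max_lag, dom.lower, None)
    iu = np.rint((t_grid - dom.lower) / fine_step).astype(int)
    il = np.rint((lo_vals - dom.lower) / fine_step).astype(int)
    aligned = (
        np.allclose(dom.lower + iu * fine_step, t_grid, atol=1e-9)
        and np.allclose(dom.lower + il * fine_step, lo_vals, atol=1e-9)
        and not np.any(iu % 2)
        and not np.any(il % 2)
    )
    if not aligned:
        raise ValueError(
            "t_grid and max_lag must land on even multiples of the fine "
            f"quadrature grid (step {fine_step})"
        )
    return C[..., iu // 2] - C[..., il // 2]  # (n, ds, n_t)


def _surface_design(I: np.ndarray, Bt: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Design columns for masked tensor pairs; rows ordered year-major."""
    n, _, n_t = I.shape
    cols = np.empty((n * n_t, pairs.shape[0]))
    for c, (j, k) in enumerate(pairs):
        cols[:, c] = (I[:, j, :] * Bt[:, k][None, :]).reshape(-1)
    return cols


# ---------------------------------------------------------------------------
# Response construction
# ---------------------------------------------------------------------------

def log_rate_curves(
    daily_counts: np.ndarray,
    basis: BasisSystem,
    curve_labels=None,
    rate_floor: float = RATE_FLOOR,
) -> FunctionalSample:
    """Smooth per-year daily counts into positive rate curves, then log them.

    ``daily_counts`` is (n_years, 365).  The smoothed rate is evaluated on the
    day-centre grid, clipped at ``rate_floor`` and projected back onto the
    basis, giving the log-mortality curves the FFLM takes as response.
    """
    counts = np.atleast_2d(np.asarray(daily_counts, dtype=float))
    if counts.shape[1] != 365:
        raise ValueError(f"expected 365 daily values per year, got {counts.shape[1]}")
    day_centres = np.arange(365) + 0.5
    from .basis import smooth  # local import to avoid cycle at module load

    rates = smooth((day_centres, counts), basis, curve_labels)
    vals = np.maximum(rates.evaluate(day_centres), rate_floor)
    log_vals = np.log(vals)
    return smooth((day_centres, log_vals), basis, curve_labels)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _year_trend_design(year_indices: np.ndarray, dim: int, year_range=None):
    """Natural-spline trend in the year index with ~dim degrees of freedom.

    The knot count is capped below the number of distinct fitted years so the
    trend can never interpolate the year means exactly (which would let a
    held-out year's trend value swing arbitrarily).
    """
    from .basis import NaturalSplineBasis

    yi = np.asarray(year_indices, dtype=float)
    lo, hi = (year_range if year_range is not None else (yi.min(), yi.max()))
    n_distinct = np.unique(yi).size
    if hi <= lo or n_distinct < 3:  # too few years: level handled by beta0
        return (
            np.zeros((yi.size, 0)),
            np.array([lo, lo + 1.0]),
            np.zeros((0, 0)),
            np.zeros((0, 0)),
        )
    n_knots = max(2, min(dim, n_distinct - 1))  # ns dimension = n_knots
    knots = np.linspace(lo, hi, n_knots)
    nsb = NaturalSplineBasis(tuple(knots))
    N = nsb.design(yi)
    Nc, Z = drop_constant_direction(N)
    P_tr = Z.T @ nsb.penalty() @ Z
    return Nc, knots, Z, P_tr


def fit_fflm(
    mortality: FunctionalSample,
    temperature: FunctionalSample,
    max_lag: float = DEFAULT_MAX_LAG,
    config: FFLMConfig | None = None,
    year_indices=None,
    year_range=None,
) -> FFLMFit:
    """Fit the historical FFLM to log-mortality and temperature curves."""
    config = config or FFLMConfig()
    if not (0.0 < max_lag <= 365.0):
        raise ValueError(f"max_lag must be in (0, 365], got {max_lag}")
    if mortality.n_curves != temperature.n_curves:
        raise ValueError(
            f"{mortality.n_curves} mortality curves vs "
            f"{temperature.n_curves} temperature curves"
        )
    n = mortality.n_curves
    if year_indices is None:
        year_indices = np.arange(1, n + 1)
    year_indices = np.asarray(year_indices, dtype=float)

    t_grid = np.linspace(0.0, 365.0, config.n_t_grid, endpoint=False) + (
        365.0 / config.n_t_grid / 2.0
    )
    n_t = t_grid.size

    # centre temperature at the across-year mean curve
    mean_coefs = temperature.coefficients.mean(axis=0)
    centred = FunctionalSample(
        temperature.basis,
        temperature.coefficients - mean_coefs[None, :],
        temperature.curve_labels,
    )

    I = historical_integrals(centred, config.s_basis, t_grid, max_lag)
    Bt = config.t_basis.design_matrix(t_grid)
    mask = band_mask(config.s_basis, config.t_basis, max_lag)
    pairs = np.argwhere(mask)
    S = _surface_design(I, Bt, pairs)

    Tc, knots, Z_t, P_tr = _year_trend_design(
        year_indices, config.trend_dimension, year_range
    )
    T_block = np.repeat(Tc, n_t, axis=0)
    B0_block = np.tile(Bt, (n, 1))

    y = mortality.evaluate(t_grid).reshape(-1)
    X = np.column_stack([T_block, B0_block, S])
    p_tr, p_b0, p_s = Tc.shape[1], Bt.shape[1], S.shape[1]

    # anisotropic penalties on the masked tensor coefficients
    Ps = penalty(config.s_basis, 2).matrix
    Pt = penalty(config.t_basis, 2).matrix
    Gs = gram_matrix(config.s_basis)
    Gt = gram_matrix(config.t_basis)
    flat = pairs[:, 0] * config.t_basis.dimension + pairs[:, 1]
    Ds = np.kron(Ps, Gt)[np.ix_(flat, flat)]
    Dt = np.kron(Gs, Pt)[np.ix_(flat, flat)]

    def make_D(lam_s, lam_t):
        D = np.zeros((X.shape[1], X.shape[1]))
        D[p_tr + p_b0 :, p_tr + p_b0 :] = lam_s * Ds + lam_t * Dt
        return D

    from .sflm import trend_stabilizer

    D0 = np.zeros((X.shape[1], X.shape[1]))
    if p_tr:
        D0[:p_tr, :p_tr] = trend_stabilizer(T_block, P_tr)

    XtX, Xty = X.T @ X, X.T @ y
    scale = np.trace(XtX[p_tr + p_b0 :, p_tr + p_b0 :]) / max(
        np.trace(Ds) + np.trace(Dt), 1e-300
    )
    if config.smoothing_parameters is not None:
        lam_s, lam_t = config.smoothing_parameters
        theta = np.linalg.solve(XtX + D0 + make_D(lam_s, lam_t), Xty)
    else:
        best = None
        grid = np.asarray(config.lambda_grid, dtype=float) * scale
        # the grid-evaluated response curves carry only n * dim(response basis)
        # independent values; using the raw grid size would make GCV treat the
        # smoothing-induced correlation as information and undersmooth badly
        n_eff = n * mortality.basis.dimension
        for ls in grid:
            for lt in grid:
                M = XtX + D0 + make_D(ls, lt)
                th = np.linalg.solve(M, Xty)
                df = np.trace(np.linalg.solve(M, XtX))
                rss = float(np.sum((y - X @ th) ** 2))
                gcv = rss / (1.0 - min(df / n_eff, 0.999)) ** 2
                if best is None or gcv < best[0]:
                    best = (gcv, ls, lt, th)
        _, lam_s, lam_t, theta = best

    fitted = (X @ theta).reshape(n, n_t)
    response = y.reshape(n, n_t)

    coef_mat = np.zeros((config.s_basis.dimension, config.t_basis.dimension))
    coef_mat[pairs[:, 0], pairs[:, 1]] = theta[p_tr + p_b0 :]
    surface = HistoricalSurface(
        config.s_basis, config.t_basis, coef_mat, max_lag, support_mask=mask
    )
    beta0 = FunctionalSample(
        config.t_basis, theta[p_tr : p_tr + p_b0][None, :], ["beta0"]
    )

    return FFLMFit(
        trend_coefs=theta[:p_tr].copy(),
        beta0=beta0,
        beta1=surface,
        residual_grid=response - fitted,
        response_grid=response,
        fitted_grid=fitted,
        t_grid=t_grid,
        chosen_smoothing=(float(lam_s), float(lam_t)),
        config=config,
        year_indices=year_indices,
        temp_mean_coefs=mean_coefs,
        temp_basis=temperature.basis,
        _trend_knots=knots,
        _trend_Z=Z_t,
        _mask_pairs=pairs,
    )


def predict_fflm(
    fit: FFLMFit, temperature: FunctionalSample, year_indices
) -> FFLMPrediction:
    """Predicted mortality curves exp(trend + beta0 + historical integral)."""
    year_indices = np.asarray(year_indices, dtype=float)
    if temperature.n_curves != year_indices.size:
        raise ValueError("one temperature curve per requested year is required")
    lo, hi = fit._trend_knots[0], fit._trend_knots[-1]
    if np.any(year_indices < lo - 1) or np.any(year_indices > hi + 1):
        raise ValueError(
            "year index beyond the trend spline's range (+/- 1 year); "
            "refusing to extrapolate"
        )
    centred = FunctionalSample(
        temperature.basis,
        temperature.coefficients - fit.temp_mean_coefs[None, :],
        temperature.curve_labels,
    )
    I = historical_integrals(centred, fit.config.s_basis, fit.t_grid, fit.beta1.max_lag)
    Bt = fit.config.t_basis.design_matrix(fit.t_grid)
    S = _surface_design(I, Bt, fit._mask_pairs)
    surf_term = (
        S @ fit.beta1.coefficients[fit._mask_pairs[:, 0], fit._mask_pairs[:, 1]]
    ).reshape(year_indices.size, fit.t_grid.size)
    if fit.trend_coefs.size:
        N = natural_spline_design(year_indices, fit._trend_knots) @ fit._trend_Z
        trend = N @ fit.trend_coefs
    else:
        trend = np.zeros(year_indices.size)
    b0 = fit.beta0.evaluate(fit.t_grid)[0]
    log_pred = trend[:, None] + b0[None, :] + surf_term
    return FFLMPrediction(np.exp(log_pred), fit.t_grid, year_indices)


def surface_heatmap_table(fit: FFLMFit, s_grid, t_grid) -> pd.DataFrame:
    """Long-format (s, t, value) table of the coefficient surface."""
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    vals = fit.beta1.evaluate(s_grid, t_grid)
    S, T = np.meshgrid(s_grid, t_grid, indexing="ij")
    return pd.DataFrame({"s": S.ravel(), "t": T.ravel(), "value": vals.ravel()})
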