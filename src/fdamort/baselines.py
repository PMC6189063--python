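"""Classical comparator models: lag-1 temperature GAMs and a DLNM cross-basis.

These are the models the functional fits are benchmarked against: generalized
additive models of log daily counts on a single lag-1 temperature summary
(min / mean / max / diurnal range), and a distributed lag non-linear model
whose cross-basis uses B-spline knots at the 10th/75th/90th temperature
percentiles and log-spaced lag knots over 60 days, optionally interacted with
one day-of-year harmonic.  All comparators share the SFLM's Gaussian-on-log-
counts estimation so the cross-validated RMSEs compare like with like on the
count scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .basis import (
    BasisSystem,
    Interval,
    NaturalSplineBasis,
    drop_constant_direction,
    make_basis,
    natural_spline_design,
    penalty,
)
from .sflm import log_response, trend_stabilizer

__all__ = [
    "DailySummary",
    "CrossBasis",
    "BaselineFit",
    "summarize_day",
    "summarize_days",
    "fit_lag_gam",
    "build_crossbasis",
    "fit_dlnm",
    "predict_baseline",
]

GAM_KINDS = ("gam_min", "gam_mean", "gam_max", "gam_dr")
SUMMARY_COLS = {"gam_min": "t_min", "gam_mean": "t_mean",
                "gam_max": "t_max", "gam_dr": "diurnal_range"}
MIN_HOURS = 18


@dataclass(frozen=True)
class DailySummary:
    date: object
    t_min: float
    t_mean: float
    t_max: float
    diurnal_range: float
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if not (self.t_min <= self.t_mean <= self.t_max):
                raise ValueError("summary requires t_min <= t_mean <= t_max")


@dataclass
class CrossBasis:
    """Lag-summed tensor-product design for the DLNM."""

    temp_basis: BasisSystem
    lag_basis: BasisSystem
    max_lag: int
    design: np.ndarray  # (n_days, dim_temp * dim_lag)
    complete: np.ndarray  # rows with a full lag history
    lag_weights: np.ndarray  # (max_lag + 1, dim_lag) lag-basis values


@dataclass
class BaselineFit:
    kind: str
    coefficients: np.ndarray
    trend_coefs: np.ndarray
    intercept: float
    residuals: np.ndarray
    chosen_smoothing: float
    smooth_edf: float = float("nan")  # effective df of the penalized block
    # prediction state
    _trend_knots: np.ndarray = None
    _trend_Z: np.ndarray = None
    _anchor: object = None
    _data_day_range: tuple = None
    _trend_spacing: float = 91.0
    _smooth_basis: BasisSystem = None
    _smooth_Z: np.ndarray = None
    _crossbasis: CrossBasis = None
    _block_Zs: list = None
    _with_doy: bool = False
    _dates: pd.DatetimeIndex = None


# ---------------------------------------------------------------------------
# Daily summaries
# ---------------------------------------------------------------------------

def summarize_day(hourly: Sequence[tuple[float, float]], date=None) -> DailySummary:
    """Min/mean/max/diurnal-range over one day's hourly readings.

    Days with fewer than 18 of 24 values present are flagged missing rather
    than silently summarized.
    """
    temps = np.asarray([t for _, t in hourly], dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size < MIN_HOURS:
        return DailySummary(date, np.nan, np.nan, np.nan, np.nan, missing=True)
    t_min, t_max = float(temps.min()), float(temps.max())
    return DailySummary(date, t_min, float(temps.mean()), t_max, t_max - t_min)


def summarize_days(hourly: pd.DataFrame) -> pd.DataFrame:
    """Per-day summaries from a (timestamp, temperature) frame."""
    df = hourly.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    rows = []
    for date, grp in df.groupby("date"):
        hours = pd.to_datetime(grp["timestamp"]).dt.hour.to_numpy()
        s = summarize_day(list(zip(hours, grp["temperature"].to_numpy())), date)
        rows.append(
            {
                "date": date,
                "t_min": s.t_min,
                "t_mean": s.t_mean,
                "t_max": s.t_max,
                "diurnal_range": s.diurnal_range,
                "missing": s.missing,
            }
        )
    return pd.DataFrame(rows).set_index("date")


# ---------------------------------------------------------------------------
# Shared penalized-LS machinery
# ---------------------------------------------------------------------------

def _trend_block(dates: pd.DatetimeIndex, spacing: float = 91.0, date_range=None):
    # knots every `spacing` observed days (calendar abscissa), matching the
    # SFLM's trend so season gaps never leave a spline column without data
    from .sflm import _trend_knots

    knots, start = _trend_knots(dates, spacing, date_range)
    d = (dates - start).days.to_numpy(dtype=float)
    nsb = NaturalSplineBasis(tuple(knots))
    N = nsb.design(d)
    Nc, Z = drop_constant_direction(N)
    P_tr = Z.T @ nsb.penalty() @ Z
    d_range = (float(d.min()), float(d.max()))
    return Nc, knots, Z, start, P_tr, d_range


def _gcv_fit(X, y, D, lam_grid, lam_scale, D0=None):
    XtX, Xty = X.T @ X, X.T @ y
    base = XtX if D0 is None else XtX + D0
    n = y.size
    best = None
    for lam in np.asarray(lam_grid, dtype=float) * lam_scale:
        M = base + lam * D
        theta = np.linalg.solve(M, Xty)
        df = np.trace(np.linalg.solve(M, XtX))
        rss = float(np.sum((y - X @ theta) ** 2))
        gcv = n * rss / (n - df) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, theta, df)
    return best[1], best[2], best[3]


LAMBDA_GRID = tuple(np.logspace(-6.0, 6.0, 25))


def _block_edf(X: np.ndarray, Dtot: np.ndarray, off: int) -> float:
    """Effective df of the penalized block: trace of the block of the hat map."""
    XtX = X.T @ X
    A = np.linalg.solve(XtX + Dtot, XtX)
    return float(np.trace(A[off:, off:]))


# ---------------------------------------------------------------------------
# Lag-1 summary GAMs
# ---------------------------------------------------------------------------

def fit_lag_gam(
    counts: pd.Series,
    lagged_summaries: pd.DataFrame,
    which: str,
    n_basis: int = 10,
    trend_date_range=None,
) -> BaselineFit:
    """GAM of log counts on the lag-1 value of one temperature summary.

    ``lagged_summaries`` is indexed like ``counts`` and already holds day
    i-1's summary in row i.  The summary enters through a penalized cubic
    B-spline with ``n_basis`` functions (second-derivative penalty, GCV).
    """
    kind = which if which.startswith("gam_") else f"gam_{which}"
    if kind not in GAM_KINDS:
        raise ValueError(f"unknown GAM kind {which!r}; expected one of {GAM_KINDS}")
    col = SUMMARY_COLS[kind]
    counts = counts.sort_index()
    x = lagged_summaries.reindex(counts.index)[col].to_numpy(dtype=float)
    miss = ~np.isfinite(x)
    if miss.mean() > 0.10:
        raise ValueError(
            f"summary {col!r} missing for {miss.mean():.0%} of days (> 10%)"
        )
    keep = ~miss
    dates = pd.DatetimeIndex(counts.index)[keep]
    y = log_response(counts.to_numpy()[keep])
    x = x[keep]

    T, knots, Z_t, anchor, P_tr, d_range = _trend_block(
        dates, date_range=trend_date_range
    )
    lo, hi = x.min(), x.max()
    pad = 1e-6 * max(1.0, hi - lo)
    sb = make_basis(Interval(lo - pad, hi + pad), n_basis - 4, order=4)
    Sm_raw = sb.design_matrix(x)
    Sm, Z_s = drop_constant_direction(Sm_raw)

    X = np.column_stack([np.ones(y.size), T, Sm])
    P = Z_s.T @ penalty(sb, 2).matrix @ Z_s
    D = np.zeros((X.shape[1], X.shape[1]))
    off = 1 + T.shape[1]
    D[off:, off:] = P
    D0 = np.zeros_like(D)
    D0[1:off, 1:off] = trend_stabilizer(T, P_tr)
    lam_scale = np.trace(X[:, off:].T @ X[:, off:]) / max(np.trace(P), 1e-300)
    lam, theta, _ = _gcv_fit(X, y, D, LAMBDA_GRID, lam_scale, D0=D0)
    edf = _block_edf(X, D0 + lam * D, off)

    resid = y - X @ theta
    return BaselineFit(
        kind=kind,
        coefficients=theta[off:].copy(),
        trend_coefs=theta[1:off].copy(),
        intercept=float(theta[0]),
        residuals=resid,
        chosen_smoothing=float(lam),
        smooth_edf=edf,
        _trend_knots=knots,
        _trend_Z=Z_t,
        _anchor=anchor,
        _data_day_range=d_range,
        _smooth_basis=sb,
        _smooth_Z=Z_s,
        _dates=dates,
    )


def _gam_linear_predictor(fit: BaselineFit, dates, x: np.ndarray) -> np.ndarray:
    d = (pd.DatetimeIndex(dates) - fit._anchor).days.to_numpy(dtype=float)
    d = np.clip(d, fit._data_day_range[0], fit._data_day_range[1])
    T = natural_spline_design(d, fit._trend_knots) @ fit._trend_Z
    dom = fit._smooth_basis.domain
    x = np.clip(x, dom.lower, dom.upper)  # clamp to the observed range
    Sm = fit._smooth_basis.design_matrix(x) @ fit._smooth_Z
    return fit.intercept + T @ fit.trend_coefs + Sm @ fit.coefficients


def partial_effect(fit: BaselineFit, x_grid) -> np.ndarray:
    """The fitted smooth temperature effect on the log scale."""
    x_grid = np.asarray(x_grid, dtype=float)
    Sm = fit._smooth_basis.design_matrix(x_grid) @ fit._smooth_Z
    return Sm @ fit.coefficients


# ---------------------------------------------------------------------------
# DLNM cross-basis
# ---------------------------------------------------------------------------

def build_crossbasis(
    daily_temps: np.ndarray,
    max_lag: int = 60,
    temp_percentiles: tuple = (10, 75, 90),
    n_lag_knots: int = 5,
    temp_order: int = 4,
) -> CrossBasis:
    """Cross-basis design: row i sums temp-basis(x_{i-lag}) x lag-basis(lag).

    Temperature knots sit at the given percentiles of the observed series;
    lag knots are equally spaced on the log(lag+1) scale over [0, max_lag].
    """
    x = np.asarray(daily_temps, dtype=float)
    n = x.size
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} >= series length {n}")
    lo, hi = x.min(), x.max()
    pad = 1e-6 * max(1.0, hi - lo)
    t_knots = tuple(np.percentile(x, temp_percentiles))
    temp_basis = BasisSystem(
        Interval(lo - pad, hi + pad), order=temp_order, interior_knots=t_knots
    )
    log_knots = np.linspace(0.0, np.log(max_lag + 1.0), n_lag_knots + 2)[1:-1]
    lag_knots = tuple(np.exp(log_knots) - 1.0)
    lag_basis = BasisSystem(
        Interval(0.0, float(max_lag)), order=4, interior_knots=lag_knots
    )

    Btemp = temp_basis.design_matrix(x)  # (n, dim_temp)
    lags = np.arange(max_lag + 1, dtype=float)
    W = lag_basis.design_matrix(lags)  # (max_lag+1, dim_lag)
    dt, dl = temp_basis.dimension, lag_basis.dimension
    design = np.zeros((n, dt * dl))
    for lag in range(max_lag + 1):
        shifted = np.zeros((n, dt))
        shifted[lag:] = Btemp[: n - lag]
        design += np.einsum("ij,k->ijk", shifted, W[lag]).reshape(n, dt * dl)
    complete = np.arange(n) >= max_lag
    return CrossBasis(temp_basis, lag_basis, int(max_lag), design, complete, W)


def _reduce_rank(M: np.ndarray, tol: float = 1e-9):
    """Reparameterize a penalized block to full column rank.

    The lag-summed tensor design carries exact collinear directions (both
    marginal bases are partitions of unity, so whole coefficient patterns map
    to constant columns).  Column-centre, then keep the right singular vectors
    with non-negligible singular values; the returned Z is orthonormal so a
    ridge penalty in the reduced space matches a ridge on the original block
    restricted to its identifiable part.
    """
    Mc = M - M.mean(axis=0, keepdims=True)
    _, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    keep = s > tol * s[0]
    return M @ Vt[keep].T, Vt[keep].T


def _dlnm_raw_block(crossbasis_rows: np.ndarray, dates, with_doy: bool) -> np.ndarray:
    blocks = [crossbasis_rows]
    if with_doy:
        doy = pd.DatetimeIndex(dates).dayofyear.to_numpy(dtype=float)
        blocks.append(crossbasis_rows * np.sin(2 * np.pi * doy / 365.0)[:, None])
        blocks.append(crossbasis_rows * np.cos(2 * np.pi * doy / 365.0)[:, None])
    return np.column_stack(blocks)


def fit_dlnm(
    counts: pd.Series,
    crossbasis: CrossBasis,
    with_doy_interaction: bool = False,
    trend_date_range=None,
    lambda_grid=LAMBDA_GRID,
) -> BaselineFit:
    """Ridge-penalized DLNM of log counts on the cross-basis (GCV lambda).

    With ``with_doy_interaction`` the cross-basis columns are additionally
    modulated by one sine/cosine day-of-year harmonic, letting the
    exposure-lag-response vary over the season.
    """
    counts = counts.sort_index()
    dates = pd.DatetimeIndex(counts.index)
    if dates.size != crossbasis.design.shape[0]:
        raise ValueError("counts and cross-basis cover different numbers of days")
    keep = crossbasis.complete
    y = log_response(counts.to_numpy()[keep])
    dates_k = dates[keep]

    T, knots, Z_t, anchor, P_tr, d_range = _trend_block(
        dates_k, date_range=trend_date_range
    )

    Braw = _dlnm_raw_block(crossbasis.design[keep], dates_k, with_doy_interaction)
    Bred, Z_cb = _reduce_rank(Braw)

    X = np.column_stack([np.ones(y.size), T, Bred])
    off = 1 + T.shape[1]
    p_pen = X.shape[1] - off
    D = np.zeros((X.shape[1], X.shape[1]))
    D[off:, off:] = np.eye(p_pen)  # ridge on the identifiable cross-basis part
    D0 = np.zeros_like(D)
    D0[1:off, 1:off] = trend_stabilizer(T, P_tr)
    lam_scale = np.trace(X[:, off:].T @ X[:, off:]) / p_pen
    XtX = X.T @ X
    lam_min = np.min(lambda_grid) * lam_scale
    cond = np.linalg.cond(XtX + D0 + lam_min * D)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"singular penalized DLNM system (condition number {cond:.2e})"
        )
    lam, theta, _ = _gcv_fit(X, y, D, lambda_grid, lam_scale, D0=D0)
    edf = _block_edf(X, D0 + lam * D, off)

    resid = y - X @ theta
    return BaselineFit(
        kind="dlnm_doy" if with_doy_interaction else "dlnm",
        coefficients=theta[off:].copy(),
        trend_coefs=theta[1:off].copy(),
        intercept=float(theta[0]),
        residuals=resid,
        chosen_smoothing=float(lam),
        smooth_edf=edf,
        _trend_knots=knots,
        _trend_Z=Z_t,
        _anchor=anchor,
        _data_day_range=d_range,
        _crossbasis=crossbasis,
        _block_Zs=[Z_cb],
        _with_doy=with_doy_interaction,
        _dates=dates_k,
    )


def _dlnm_linear_predictor(fit: BaselineFit, dates, design_rows: np.ndarray):
    d = (pd.DatetimeIndex(dates) - fit._anchor).days.to_numpy(dtype=float)
    d = np.clip(d, fit._data_day_range[0], fit._data_day_range[1])
    T = natural_spline_design(d, fit._trend_knots) @ fit._trend_Z
    Xb = _dlnm_raw_block(design_rows, dates, fit._with_doy) @ fit._block_Zs[0]
    return fit.intercept + T @ fit.trend_coefs + Xb @ fit.coefficients


def cumulative_exposure_response(fit: BaselineFit, temp_grid) -> np.ndarray:
    """Cumulative (lag-summed) log-scale effect of a sustained temperature.

    For the day-of-year variant the harmonic factors are evaluated at their
    annual mean (zero), i.e. the season-average response is returned.
    """
    temp_grid = np.asarray(temp_grid, dtype=float)
    cb = fit._crossbasis
    Btemp = cb.temp_basis.design_matrix(
        np.clip(temp_grid, cb.temp_basis.domain.lower, cb.temp_basis.domain.upper)
    )
    Wsum = cb.lag_weights.sum(axis=0)  # (dim_lag,)
    rows = np.einsum("ij,k->ijk", Btemp, Wsum).reshape(temp_grid.size, -1)
    if fit._with_doy:
        rows = np.column_stack([rows, np.zeros_like(rows), np.zeros_like(rows)])
    eff = rows @ fit._block_Zs[0] @ fit.coefficients
    return eff - eff.mean()


def predict_baseline(fit: BaselineFit, dates, exposure) -> np.ndarray:
    """Predicted counts for new days.

    ``exposure`` is a lag-1 summary frame for GAM kinds, or pre-built
    cross-basis design rows for DLNM kinds.
    """
    if fit.kind in GAM_KINDS:
        x = exposure[SUMMARY_COLS[fit.kind]].to_numpy(dtype=float)
        return np.exp(_gam_linear_predictor(fit, dates, x))
    return np.exp(_dlnm_linear_predictor(fit, dates, exposure))
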