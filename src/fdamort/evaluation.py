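"""Blocked (leave-one-year-out) cross-validated RMSE on the count scale.

Folds are calendar years, respecting the serial dependence of mortality time
series.  For each fold the model is refit on the remaining years and the
held-out year is predicted on the count scale (functional predictions are
discretized to daily values first); held-out squared errors are pooled across
folds before taking the root, giving one RMSE per model plus per-fold
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import (
    GAM_KINDS,
    build_crossbasis,
    fit_dlnm,
    fit_lag_gam,
    predict_baseline,
    summarize_days,
)
from .fflm import FFLMConfig, default_mortality_basis, fit_fflm, log_rate_curves, predict_fflm
from .sflm import SFLMConfig, fit_sflm, predict_sflm
from .synthetic import AnnualDataset, SummerDataset

__all__ = ["FoldPlan", "rmse", "blocked_cv_rmse", "make_year_folds", "MODEL_SPECS"]

MODEL_SPECS = ("sflm", "fflm", "gam_min", "gam_mean", "gam_max", "gam_dr",
               "dlnm", "dlnm_doy")


def rmse(predicted, observed) -> float:
    """Root mean squared error; rejects length mismatches and missing values."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: predicted {p.shape} vs observed {o.shape}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise ValueError("missing or non-finite values in RMSE input")
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass
class FoldPlan:
    """One fold per calendar year."""

    fold_labels: np.ndarray  # per-observation year identifier

    def __post_init__(self) -> None:
        self.fold_labels = np.asarray(self.fold_labels)
        self.folds = np.unique(self.fold_labels)

    @property
    def n_folds(self) -> int:
        return self.folds.size

    def masks(self):
        for f in self.folds:
            test = self.fold_labels == f
            yield f, ~test, test


def make_year_folds(dates) -> FoldPlan:
    return FoldPlan(pd.DatetimeIndex(dates).year.to_numpy())


# ---------------------------------------------------------------------------
# Per-model fold fitters
# ---------------------------------------------------------------------------

def _cv_summer(model_spec: str, data: SummerDataset, fold_plan: FoldPlan):
    counts, exposures = data.counts, data.exposures
    dates = pd.DatetimeIndex(counts.index)
    date_range = (dates.min(), dates.max())
    summaries = None
    if model_spec in GAM_KINDS:
        summaries = summarize_days(data.hourly)
        # lag-1 alignment: row for response day i holds day i-1's summary
        lagged = summaries.copy()
        lagged.index = lagged.index + pd.Timedelta(days=1)
        lagged = lagged.reindex(counts.index)

    def run_fold(train, test):
        tr_counts = counts[train]
        te_dates = dates[test]
        if model_spec == "sflm":
            from .basis import FunctionalSample

            tr_exp = FunctionalSample(
                exposures.basis,
                exposures.coefficients[train],
                [l for l, m in zip(exposures.curve_labels, train) if m],
            )
            te_exp = FunctionalSample(
                exposures.basis,
                exposures.coefficients[test],
                [l for l, m in zip(exposures.curve_labels, test) if m],
            )
            cfg = SFLMConfig(trend_date_range=date_range)
            fit = fit_sflm(tr_counts, tr_exp, cfg)
            pred = predict_sflm(fit, te_exp, te_dates)
        else:
            fit = fit_lag_gam(
                tr_counts, lagged[train], model_spec, trend_date_range=date_range
            )
            pred = predict_baseline(fit, te_dates, lagged[test])
        return pred, counts.to_numpy(dtype=float)[test]

    return run_fold


def _cv_annual(model_spec: str, data: AnnualDataset, fold_plan: FoldPlan):
    daily = data.daily
    dates = pd.DatetimeIndex(daily["timestamp"])
    counts = pd.Series(
        daily["deaths"].to_numpy(dtype=float), index=dates, name="deaths"
    )
    n_years = data.scenario.n_years
    years = np.arange(n_years)
    year_of_row = np.repeat(years, 365)
    # days without a full 60-day history are excluded from scoring for all
    # models so FFLM and DLNM RMSEs pool identical days
    score_ok = np.arange(dates.size) >= 60

    if model_spec in ("dlnm", "dlnm_doy"):
        cb = build_crossbasis(daily["temperature"].to_numpy(dtype=float), max_lag=60)
        date_range = (dates.min(), dates.max())

        def run_fold(train, test):
            from .baselines import CrossBasis

            tr_cb = CrossBasis(
                cb.temp_basis,
                cb.lag_basis,
                cb.max_lag,
                cb.design[train],
                cb.complete[train],
                cb.lag_weights,
            )
            fit = fit_dlnm(
                counts[train],
                tr_cb,
                with_doy_interaction=(model_spec == "dlnm_doy"),
                trend_date_range=date_range,
            )
            sel = test & score_ok
            pred = predict_baseline(fit, dates[sel], cb.design[sel])
            return pred, counts.to_numpy()[sel]

        return run_fold

    if model_spec == "fflm":
        cfg = FFLMConfig()
        log_mort_all = log_rate_curves(data.counts_by_year, default_mortality_basis())
        temp = data.temperature_sample

        def run_fold(train, test):
            from .basis import FunctionalSample

            tr_years = years[np.unique(year_of_row[train])] + 1
            te_years = years[np.unique(year_of_row[test])] + 1
            tr_mort = FunctionalSample(
                log_mort_all.basis, log_mort_all.coefficients[tr_years - 1]
            )
            tr_temp = FunctionalSample(
                temp.basis, temp.coefficients[tr_years - 1]
            )
            te_temp = FunctionalSample(
                temp.basis, temp.coefficients[te_years - 1]
            )
            fit = fit_fflm(
                tr_mort,
                tr_temp,
                config=cfg,
                year_indices=tr_years,
                year_range=(1, n_years),
            )
            pred = predict_fflm(fit, te_temp, te_years)
            series = pred.discretize()
            sel_rows = test & score_ok
            within = sel_rows[test]
            return series[within], counts.to_numpy()[sel_rows]

        return run_fold

    raise ValueError(
        f"model_spec {model_spec!r} not applicable to annual data"
    )


def blocked_cv_rmse(
    model_spec: str, data, fold_plan: FoldPlan
) -> tuple[float, pd.DataFrame]:
    """Leave-one-year-out CV RMSE of a model's count-scale predictions.

    Returns the pooled RMSE (square root of the mean of all held-out squared
    errors) and a per-fold table.  A fold whose fit fails is reported in the
    table and invalidates the overall RMSE (NaN).

    ``model_spec`` is one of MODEL_SPECS, or a callable ``(data, fold_plan) ->
    run_fold`` where ``run_fold(train_mask, test_mask)`` returns the fold's
    (predictions, observations) on the count scale.
    """
    if callable(model_spec):
        run_fold = model_spec(data, fold_plan)
    elif isinstance(data, SummerDataset):
        run_fold = _cv_summer(model_spec, data, fold_plan)
    elif isinstance(data, AnnualDataset):
        run_fold = _cv_annual(model_spec, data, fold_plan)
    else:
        raise TypeError(f"unsupported data bundle {type(data).__name__}")

    all_sq, rows, failed = [], [], False
    for fold, train, test in fold_plan.masks():
        if not np.any(train):
            raise ValueError(f"fold {fold!r} leaves an empty training set")
        try:
            pred, obs = run_fold(train, test)
            sq = (np.asarray(pred) - np.asarray(obs)) ** 2
            all_sq.append(sq)
            rows.append(
                {
                    "fold": fold,
                    "n": sq.size,
                    "rmse": float(np.sqrt(sq.mean())),
                    "error": "",
                }
            )
        except Exception as exc:  # report per fold, invalidate overall
            failed = True
            rows.append({"fold": fold, "n": 0, "rmse": np.nan, "error": str(exc)})
    per_fold = pd.DataFrame(rows)
    if failed:
        return float("nan"), per_fold
    pooled = float(np.sqrt(np.concatenate(all_sq).mean()))
    return pooled, per_fold
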