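"""Climate covariates: three annual attributes x five time-series measures.

From ~30 years of monthly data per cell, three annual attributes are derived:

* minimum temperature — the coldest month's mean daily minimum (degC);
* drought — annual potential evapotranspiration minus total precipitation
  (mm), PET by a pluggable estimator defaulting to Thornthwaite;
* growing degree days — accumulated monthly mean temperature above 5.5 degC,
  weighted by month length.

Each attribute is then summarized by five measures: mean, detrended variance
(residual variance about an OLS line), lag-1 autocorrelation, long-term trend
(OLS slope per year), and a fat-tail statistic — the ratio of the central 95%
to the central 75% quantile range, larger when extremes are relatively
frequent.  This yields the 15 climate covariates used by the regressions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GDD_THRESHOLD_C = 5.5
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

CLIMATE_COLUMNS = ["Min.temp", "Drought", "GDD",
                   "varT", "varD", "varG",
                   "autoT", "autoD", "autoG",
                   "LTTT", "LTTD", "LTTG",
                   "FtailT", "FtailD", "FtailG"]


@dataclass
class ClimateSeries:
    """Annualized climate attributes for one cell."""

    cell: object
    years: np.ndarray
    annual_min_temp: np.ndarray
    annual_drought: np.ndarray
    annual_gdd: np.ndarray


# ---------------------------------------------------------------------------
# PET (Thornthwaite) and annualization
# ---------------------------------------------------------------------------

def _daylength_hours(latitude_deg: float) -> np.ndarray:
    """Mean daylength per calendar month from solar declination."""
    mid_day = np.cumsum(DAYS_IN_MONTH) - DAYS_IN_MONTH / 2.0
    decl = 0.409 * np.sin(2.0 * np.pi * mid_day / 365.0 - 1.39)
    lat = np.deg2rad(latitude_deg)
    cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_ws)


def thornthwaite_pet(tmean_monthly: np.ndarray, latitude_deg: float = 54.0) -> np.ndarray:
    """Monthly Thornthwaite PET (mm) from 12 monthly mean temperatures.

    Accepts shape (..., 12); the heat index is computed per row of 12 months.
    """
    t = np.asarray(tmean_monthly, dtype=float)
    tp = np.maximum(t, 0.0)
    heat = np.sum((tp / 5.0) ** 1.514, axis=-1, keepdims=True)
    a = (6.75e-7 * heat ** 3 - 7.71e-5 * heat ** 2 + 1.792e-2 * heat + 0.49239)
    daylen = _daylength_hours(latitude_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (daylen / 12.0) * (DAYS_IN_MONTH / 30.0) * \
            np.where(heat > 0, (10.0 * tp / np.where(heat > 0, heat, 1.0)) ** a, 0.0)
    return np.where(tp > 0, pet, 0.0)


def annualize(monthly: pd.DataFrame, latitude_deg: float = 54.0,
              pet=thornthwaite_pet,
              days_in_month: np.ndarray = DAYS_IN_MONTH) -> ClimateSeries:
    """Annualize the monthly rows of a single cell.

    ``monthly`` needs columns cell_id, year, month, tmin_c, tmean_c,
    precip_mm with all 12 months of every year present.
    """
    cells = monthly["cell_id"].unique()
    if len(cells) != 1:
        raise ValueError("annualize expects rows for exactly one cell")
    df = monthly.sort_values(["year", "month"])
    years = np.sort(df["year"].unique())
    counts = df.groupby("year")["month"].nunique()
    gaps = counts[counts != 12]
    if len(gaps):
        raise ValueError(f"incomplete years for cell {cells[0]!r}: "
                         f"{dict(gaps)} (need 12 months each)")
    tmin = df["tmin_c"].to_numpy().reshape(len(years), 12)
    tmean = df["tmean_c"].to_numpy().reshape(len(years), 12)
    precip = df["precip_mm"].to_numpy().reshape(len(years), 12)
    gdd = np.sum(np.maximum(tmean - GDD_THRESHOLD_C, 0.0) * days_in_month, axis=1)
    pet_y = pet(tmean, latitude_deg).sum(axis=1)
    return ClimateSeries(cells[0], years,
                         annual_min_temp=tmin.min(axis=1),
                         annual_drought=pet_y - precip.sum(axis=1),
                         annual_gdd=gdd)


# ---------------------------------------------------------------------------
# Time-series measures (operate on the last axis; accept 1-D or 2-D input)
# ---------------------------------------------------------------------------

def ts_mean(series) -> np.ndarray | float:
    return np.mean(np.asarray(series, dtype=float), axis=-1)


def _ols_fit(x: np.ndarray):
    t = np.arange(x.shape[-1], dtype=float)
    t = t - t.mean()
    denom = np.sum(t ** 2)
    xc = x - x.mean(axis=-1, keepdims=True)
    slope = np.sum(xc * t, axis=-1) / denom
    resid = xc - slope[..., None] * t
    return slope, resid


def ts_trend(series) -> np.ndarray | float:
    """OLS slope of value on year (per time step)."""
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("trend needs at least 3 time points")
    return _ols_fit(x)[0]


def ts_detrended_var(series) -> np.ndarray | float:
    """Residual variance about the OLS trend line, divisor n-2."""
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if n < 3:
        raise ValueError("detrended variance needs at least 3 time points")
    _, resid = _ols_fit(x)
    return np.sum(resid ** 2, axis=-1) / (n - 2)


def ts_lag1(series) -> np.ndarray | float:
    """Pearson correlation of x_t with x_{t-1}; NaN for constant series."""
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 4:
        raise ValueError("lag-1 autocorrelation needs at least 4 time points")
    a = x[..., 1:]
    b = x[..., :-1]
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt(np.sum(am ** 2, axis=-1) * np.sum(bm ** 2, axis=-1))
    flat_denom = np.atleast_1d(denom)
    if np.any(flat_denom == 0):
        warnings.warn("constant series: lag-1 autocorrelation undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sum(am * bm, axis=-1) / denom
    return np.where(denom == 0, np.nan, r) if np.ndim(r) else \
        (float("nan") if denom == 0 else float(r))


def ts_fat_tail(series, method: str = "linear") -> np.ndarray | float:
    """(Q.975 - Q.025) / (Q.875 - Q.125): relative time spent in the tails.

    ``method`` is the quantile interpolation convention (numpy names); the
    statistic is sensitive to it at short series lengths, so it is recorded
    in output metadata by the pipeline.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 8:
        raise ValueError("fat-tail statistic needs at least 8 values")
    q = np.quantile(x, [0.025, 0.125, 0.875, 0.975], axis=-1, method=method)
    denom = q[2] - q[1]
    if np.any(np.atleast_1d(denom) == 0):
        warnings.warn("zero central quantile range: fat-tail statistic NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (q[3] - q[0]) / denom
    return np.where(denom == 0, np.nan, r) if np.ndim(r) else \
        (float("nan") if denom == 0 else float(r))


# ---------------------------------------------------------------------------
# The 15-covariate table
# ---------------------------------------------------------------------------

def climate_covariates(monthly: pd.DataFrame, latitude_deg: float = 54.0,
                       pet=thornthwaite_pet,
                       quantile_method: str = "linear") -> pd.DataFrame:
    """One row per cell with the 15 named climate covariates.

    Columns: Min.temp, Drought, GDD (means), var*/auto*/LTT*/Ftail* for
    T(emperature), D(rought), G(rowing degree days).
    """
    pieces = {"cell_id": [], "T": [], "D": [], "G": []}
    for cell, df in monthly.groupby("cell_id", sort=False):
        cs = annualize(df, latitude_deg=latitude_deg, pet=pet)
        pieces["cell_id"].append(cell)
        pieces["T"].append(cs.annual_min_temp)
        pieces["D"].append(cs.annual_drought)
        pieces["G"].append(cs.annual_gdd)
    T = np.asarray(pieces["T"])
    D = np.asarray(pieces["D"])
    G = np.asarray(pieces["G"])
    out = pd.DataFrame({"cell_id": pieces["cell_id"]})
    for mean_name, arr in zip(["Min.temp", "Drought", "GDD"], [T, D, G]):
        out[mean_name] = ts_mean(arr)
    for suffix, arr in zip("TDG", [T, D, G]):
        out[f"var{suffix}"] = ts_detrended_var(arr)
    for suffix, arr in zip("TDG", [T, D, G]):
        out[f"auto{suffix}"] = ts_lag1(arr)
    for suffix, arr in zip("TDG", [T, D, G]):
        out[f"LTT{suffix}"] = ts_trend(arr)
    for suffix, arr in zip("TDG", [T, D, G]):
        out[f"Ftail{suffix}"] = ts_fat_tail(arr, method=quantile_method)
    out.attrs["quantile_method"] = quantile_method
    return out[["cell_id"] + CLIMATE_COLUMNS]
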