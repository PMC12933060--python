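"""Quality-controlled daily flux observations from towers and aircraft.

Turns half-hourly tower eddy-covariance series and 1-Hz airborne transect
samples into a single table of daily 500-m flux observations: the upscaling
training data.  Includes the strict >80% daily-coverage rule for towers, the
midday [10:00, 14:00) window and per-pixel pooling for airborne samples, and
the affine midday-to-daily CO2 conversion with first-order uncertainty
propagation (CH4 is treated as constant through the day).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

HALF_HOURS_PER_DAY = 48
MIDDAY_WINDOW = (10.0, 14.0)  # [start, end) hours, local time

OBS_COLUMNS = ["pixel_row", "pixel_col", "date", "gas", "mean", "sd", "n", "source"]


@dataclass
class DielConversion:
    """Midday-to-daily CO2 conversion y = a*x + b with coefficient SEs.

    Defaults are the published tower-derived fit (slope 0.27 +/- 0.002,
    intercept 0.58 +/- 0.01 umol m-2 s-1).
    """

    a: float = 0.27
    se_a: float = 0.002
    b: float = 0.58
    se_b: float = 0.01

    def __post_init__(self):
        if self.se_a < 0 or self.se_b < 0:
            raise ValueError("standard errors must be non-negative")


def daily_from_halfhourly(series: pd.DataFrame, min_coverage: float = 0.8) -> pd.DataFrame:
    """Daily mean +/- SD per gas, keeping only days with coverage > min_coverage.

    The rule is strict: a day survives only when present/48 > min_coverage,
    so 38/48 (79.2%) is dropped while 39/48 (81.2%) is kept at the default.
    The SD is the descriptive n-1 spread of the half-hourly values.
    """
    if series.empty:
        return pd.DataFrame(columns=OBS_COLUMNS)
    df = series.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    grouped = df.groupby(["pixel_row", "pixel_col", "date", "gas"])["flux"].agg(
        mean="mean", sd="std", n="count").reset_index()
    keep = grouped["n"] / HALF_HOURS_PER_DAY > min_coverage
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("daily_from_halfhourly: dropped %d day-gas groups below coverage", n_dropped)
    out = grouped[keep].copy()
    out["sd"] = out["sd"].fillna(0.0)
    out["source"] = "tower"
    return out[OBS_COLUMNS].reset_index(drop=True)


def midday_means(series: pd.DataFrame, window=MIDDAY_WINDOW) -> pd.DataFrame:
    """Per-day midday mean of half-hourly values (for diel-fit pairs)."""
    df = series.copy()
    ts = pd.to_datetime(df["timestamp"])
    hours = ts.dt.hour + ts.dt.minute / 60.0
    df = df[(hours >= window[0]) & (hours < window[1])]
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    return df.groupby(["pixel_row", "pixel_col", "date", "gas"])["flux"].mean().reset_index(
        name="midday_mean")


def fit_midday_daily(pairs) -> DielConversion:
    """OLS fit of daily mean on midday mean, with coefficient standard errors.

    ``pairs`` is a sequence of (midday_mean, daily_mean) tuples or a 2-column
    array.  Requires >=3 pairs and non-degenerate midday means.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (midday, daily) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("midday means have zero variance; slope not identifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = model.params
    se_b, se_a = model.bse
    # a perfect fit leaves residual DoF with zero variance -> SEs are 0, not nan
    if not np.isfinite(se_a):
        se_a = 0.0
    if not np.isfinite(se_b):
        se_b = 0.0
    return DielConversion(a=float(a), se_a=float(se_a), b=float(b), se_b=float(se_b))


def grid_airborne(samples: pd.DataFrame, grid_shape: tuple[int, int],
                  midday_window=MIDDAY_WINDOW) -> pd.DataFrame:
    """Pool 1-Hz airborne samples into per-pixel midday means.

    Only samples with timestamps inside the midday window contribute; all
    samples in the same (pixel, date, gas) are pooled across flights before
    computing the mean, n-1 SD and count.  Samples off the grid are skipped
    with a logged count.
    """
    cols = ["pixel_row", "pixel_col", "date", "gas", "midday_mean", "sd", "n"]
    if samples.empty:
        return pd.DataFrame(columns=cols)
    df = samples.copy()
    ts = pd.to_datetime(df["timestamp"])
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    df = df[(hours >= midday_window[0]) & (hours < midday_window[1])]
    n_rows, n_cols = grid_shape
    on_grid = (
        (df["pixel_row"] >= 0) & (df["pixel_row"] < n_rows)
        & (df["pixel_col"] >= 0) & (df["pixel_col"] < n_cols)
    )
    if (~on_grid).sum():
        logger.info("grid_airborne: skipped %d off-grid samples", int((~on_grid).sum()))
    df = df[on_grid]
    if df.empty:
        return pd.DataFrame(columns=cols)
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    out = df.groupby(["pixel_row", "pixel_col", "date", "gas"])["flux"].agg(
        midday_mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out[cols]


def midday_to_daily_co2(x, var_x, conv: DielConversion):
    """Convert a midday CO2 mean to a daily mean with propagated uncertainty.

    y = a*x + b; first-order (delta-method) propagation with a, b, x
    independent gives se_y^2 = x^2 se_a^2 + se_b^2 + a^2 var_x.
    """
    x = np.asarray(x, dtype=float)
    var_x = np.asarray(var_x, dtype=float)
    if np.any(var_x < 0):
        raise ValueError("var_x must be non-negative")
    y = conv.a * x + conv.b
    se_y = np.sqrt(x**2 * conv.se_a**2 + conv.se_b**2 + conv.a**2 * var_x)
    if y.ndim == 0:
        return float(y), float(se_y)
    return y, se_y


def midday_to_daily_ch4(x):
    """Daily CH4 mean equals the midday mean (flux held constant over the day)."""
    return x


def airborne_daily(gridded: pd.DataFrame, conv: DielConversion) -> pd.DataFrame:
    """Convert gridded midday means into daily flux observations.

    CO2 goes through the affine diel conversion with the midday sample
    variance propagated; CH4 passes through unchanged.
    """
    if gridded.empty:
        return pd.DataFrame(columns=OBS_COLUMNS)
    out = []
    for gas, sub in gridded.groupby("gas"):
        sub = sub.copy()
        if gas == "CO2":
            y, se = midday_to_daily_co2(sub["midday_mean"].values,
                                        sub["sd"].values**2, conv)
            sub["mean"], sub["sd"] = y, se
        else:
            sub["mean"] = midday_to_daily_ch4(sub["midday_mean"].values)
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res["source"] = "airborne"
    return res[OBS_COLUMNS]


def merge_observations(tower_daily: pd.DataFrame, airborne_daily: pd.DataFrame) -> pd.DataFrame:
    """Concatenate tower and airborne daily observations into the training table.

    Records for the same (pixel, date, gas) from different sources are both
    kept: sources are pooled, not averaged.
    """
    parts = [df for df in (tower_daily, airborne_daily) if not df.empty]
    if not parts:
        return pd.DataFrame(columns=OBS_COLUMNS)
    for df in parts:
        missing = set(OBS_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        bad = set(df["gas"].unique()) - {"CO2", "CH4"}
        if bad:
            raise ValueError(f"unknown gas labels: {sorted(bad)}")
    return pd.concat([p[OBS_COLUMNS] for p in parts], ignore_index=True)
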