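"""Greenhouse-gas accounting and long-term trend analysis.

Converts flux grids (umol CO2 / nmol CH4 m-2 s-1) into annual mass budgets,
combines them into CO2 equivalents with the 100-y global warming potential
for nonfossil methane (27.0), computes CH4/CO2 offset ratios, aggregates by
habitat or management unit with ensemble-propagated uncertainty, and maps
long-term trends with the Mann-Kendall test and Sen's slope.

MMT (million metric tons) and Tg are the same unit, 1e12 g; the sign
convention is negative = removal from the atmosphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

G_PER_MMT = 1e12


@dataclass
class AccountingConfig:
    gwp_ch4: float = 27.0            # GWP-100, nonfossil methane
    molar_mass_co2: float = 44.01    # g mol-1
    molar_mass_ch4: float = 16.04    # g mol-1
    pixel_area: float = 2.5e5        # m2 (500 m x 500 m)
    seconds_per_year: float = 3.1536e7

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrendResult:
    s: float
    var_s: float
    tau: float
    p_value: float
    sen_slope: float
    n: int


def mass_scale(gas: str, config: AccountingConfig | None = None,
               per_pixel: bool = True) -> float:
    """Multiplier from mean flux (umol or nmol m-2 s-1) to g gas y-1.

    CO2 fluxes are in umol (1e-6 mol), CH4 in nmol (1e-9 mol).  With
    per_pixel=True the result is per 500-m pixel, otherwise per m2.
    """
    cfg = config or AccountingConfig()
    if gas == "CO2":
        mol, mm = 1e-6, cfg.molar_mass_co2
    elif gas == "CH4":
        mol, mm = 1e-9, cfg.molar_mass_ch4
    else:
        raise ValueError(f"unknown gas {gas!r}")
    area = cfg.pixel_area if per_pixel else 1.0
    return mol * mm * area * cfg.seconds_per_year


def to_mass_flux(mean_daily_flux: np.ndarray, gas: str,
                 config: AccountingConfig | None = None,
                 per_pixel: bool = True) -> np.ndarray:
    """Annual mass (g gas y-1) from an annual-mean flux array; sign preserved."""
    return np.asarray(mean_daily_flux, dtype=float) * mass_scale(gas, config, per_pixel)


def co2eq(co2_mass, ch4_mass, config: AccountingConfig | None = None):
    """Net CO2-equivalent mass: CO2 + GWP * CH4 (exactly linear in both)."""
    cfg = config or AccountingConfig()
    return np.asarray(co2_mass, dtype=float) + cfg.gwp_ch4 * np.asarray(ch4_mass, dtype=float)


def offset_ratio(ch4_mass, co2_mass, config: AccountingConfig | None = None):
    """Percent of CO2 uptake offset by CH4 emissions (in CO2eq).

    Defined as 100 * GWP*CH4 / |CO2| where the CO2 term is net uptake
    (negative); NaN where there is no net uptake.
    """
    cfg = config or AccountingConfig()
    co2 = np.asarray(co2_mass, dtype=float)
    ch4 = np.asarray(ch4_mass, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(co2 < 0, 100.0 * cfg.gwp_ch4 * ch4 / np.abs(co2), np.nan)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def aggregate_by_unit(pixel_mass: np.ndarray, unit_map: np.ndarray) -> dict:
    """Total mass per management unit, with ensemble uncertainty when possible.

    ``pixel_mass`` is either (y, x) — a single grid, SD unavailable — or
    (n_members, y, x), in which case each member is summed over the unit
    first and the mean +/- n-1 SD across member totals is returned (this
    preserves within-member spatial covariance).  NaN pixels are excluded;
    units with no finite pixel are omitted.
    """
    arr = np.asarray(pixel_mass, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.shape[1:] != unit_map.shape:
        raise ValueError("unit map shape does not match grid")
    out = {}
    for unit in np.unique(unit_map):
        sel = unit_map == unit
        vals = arr[:, sel]
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        totals = np.where(finite, vals, 0.0).sum(axis=1)
        mean = float(totals.mean())
        sd = 0.0 if len(totals) < 2 else float(totals.std(ddof=1))
        out[int(unit)] = {"total": mean, "sd": sd, "n_pixels": int(sel.sum())}
    return out


def mann_kendall(series) -> TrendResult:
    """Mann-Kendall trend test on a yearly series.

    S = sum over i<j of sign(x_j - x_i); Var(S) carries the tie correction;
    tau is tau-a without ties in x and tau-b with ties; the two-sided p-value
    uses the normal approximation with continuity correction.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Mann-Kendall needs at least 4 points")
    diffs = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diffs, k=1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    n0 = n * (n - 1) / 2.0
    if len(ties):
        t1 = np.sum(ties * (ties - 1) / 2.0)
        denom = np.sqrt((n0 - t1) * n0)  # no ties in the time index
        tau = s / denom if denom > 0 else 0.0
    else:
        tau = s / n0
    if var_s > 0:
        z = (s - np.sign(s)) / np.sqrt(var_s)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0
    return TrendResult(s=s, var_s=float(var_s), tau=float(tau),
                       p_value=min(max(p, np.finfo(float).tiny), 1.0),
                       sen_slope=sens_slope(x), n=n)


def sens_slope(series, times=None) -> float:
    """Sen's slope: the median of all pairwise slopes (x_j - x_i)/(t_j - t_i)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("Sen's slope needs at least 2 points")
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    i, j = np.triu_indices(n, k=1)
    dt_ = t[j] - t[i]
    ok = dt_ != 0
    if not ok.any():
        raise ValueError("no pair of distinct time points")
    return float(np.median((x[j] - x[i])[ok] / dt_[ok]))


def trend_map(annual_stack: np.ndarray, min_years: int = 4) -> dict:
    """Per-pixel Mann-Kendall + Sen's slope over an (years, y, x) stack.

    Pixels with fewer than ``min_years`` finite annual values yield NaN.
    Returns {"sen_slope", "tau", "p"} rasters.
    """
    stack = np.asarray(annual_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("annual_stack must be (years, y, x)")
    n_y, n_r, n_c = stack.shape
    if n_y < min_years:
        raise ValueError(f"need at least {min_years} annual layers, got {n_y}")
    sen = np.full((n_r, n_c), np.nan)
    tau = np.full((n_r, n_c), np.nan)
    p = np.full((n_r, n_c), np.nan)
    for r in range(n_r):
        for c in range(n_c):
            vals = stack[:, r, c]
            finite = np.isfinite(vals)
            if finite.sum() < min_years:
                continue
            res = mann_kendall_with_times(vals[finite], np.nonzero(finite)[0])
            sen[r, c], tau[r, c], p[r, c] = res.sen_slope, res.tau, res.p_value
    return {"sen_slope": sen, "tau": tau, "p": p}


def mann_kendall_with_times(values, times) -> TrendResult:
    """Mann-Kendall on an irregular yearly series (gaps allowed)."""
    res = mann_kendall(values)
    return TrendResult(s=res.s, var_s=res.var_s, tau=res.tau, p_value=res.p_value,
                       sen_slope=sens_slope(values, times), n=res.n)


def multi_year_mean(annual_stack: np.ndarray, sd_stack: np.ndarray | None = None):
    """Per-pixel mean over a window of annual grids.

    If per-year SD grids are supplied the composite SD is propagated under
    independence across years: sqrt(sum sd^2)/k.
    """
    stack = np.asarray(annual_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("need a non-empty (years, y, x) stack")
    mean = np.nanmean(stack, axis=0)
    if sd_stack is None:
        return mean
    sd = np.asarray(sd_stack, dtype=float)
    k = stack.shape[0]
    return mean, np.sqrt(np.nansum(sd**2, axis=0)) / k
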