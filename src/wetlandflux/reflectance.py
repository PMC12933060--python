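"""Reflectance covariate preparation: QA masking, automatic water masking by
gray-level histogram thresholding of the NIR1 band (Otsu's criterion), and
extraction of the 7-band covariates matched to each flux observation."""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .synth import ReflectanceCube

logger = logging.getLogger(__name__)

N_HISTOGRAM_BINS = 256


def apply_qa_mask(cube: ReflectanceCube, qa_good: np.ndarray | None = None) -> ReflectanceCube:
    """Exclude bad-quality pixel-days from the cube.

    An external boolean layer may be supplied; otherwise the cube's own QA
    layer is (re)applied.  Masking is idempotent: masks combine by AND.
    """
    if qa_good is None:
        qa_good = cube.qa_good
    if qa_good.shape != cube.qa_good.shape:
        raise ValueError("QA layer shape does not match cube")
    combined = cube.qa_good & qa_good
    n_bad = int(combined.size - combined.sum())
    logger.info("apply_qa_mask: %d of %d pixel-days masked (%.1f%%)",
                n_bad, combined.size, 100.0 * n_bad / combined.size)
    return replace(cube, qa_good=combined)


def water_threshold(nir1: np.ndarray, n_bins: int = N_HISTOGRAM_BINS) -> float:
    """Otsu's gray-level histogram threshold on NIR1 values.

    Candidate cuts are the interior edges of ``n_bins`` equal-width bins over
    the observed value range; the returned threshold maximizes the
    between-class variance w0*w1*(mu0 - mu1)^2 of the split {v < t} / {v >= t},
    computed exactly from the values (exhaustive search).  Ties break toward
    the lower threshold.
    """
    v = np.asarray(nir1, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    lo, hi = v.min(), v.max()
    if lo == hi:
        raise ValueError("constant image: no separable classes")
    edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    v_sorted = np.sort(v)
    csum = np.concatenate([[0.0], np.cumsum(v_sorted)])
    n = v.size
    total = csum[-1]
    k = np.searchsorted(v_sorted, edges, side="left")  # size of class {v < edge}
    valid = (k > 0) & (k < n)
    k_v = k[valid]
    mu0 = csum[k_v] / k_v
    mu1 = (total - csum[k_v]) / (n - k_v)
    w0 = k_v / n
    between = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    if between.size == 0:
        raise ValueError("no valid split found")
    best = int(np.argmax(between))  # argmax returns first maximum -> lower edge
    return float(edges[valid][best])


def _separability(values: np.ndarray, thr: float) -> float:
    """Fraction of total variance explained by the land/water split (eta^2);
    near 1 for a clearly bimodal histogram, well below for unimodal noise."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    total = v.var()
    if total == 0:
        return 0.0
    lo, hi = v[v < thr], v[v >= thr]
    w0 = len(lo) / len(v)
    return float(w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2 / total)


def mask_water(cube: ReflectanceCube, mode: str = "daily",
               min_water_frac: float = 0.01,
               min_separability: float = 0.75) -> tuple[ReflectanceCube, dict]:
    """Flag water (NIR1 below the histogram threshold) as masked.

    mode="daily" thresholds each day's QA-valid NIR1 image separately;
    mode="monthly_composite" thresholds the per-pixel monthly mean NIR1 and
    applies that month's mask to all of its days.  Returns the masked cube and
    a report with thresholds and the masked fraction; warns when the masked
    fraction suggests no real water class.
    """
    nir1 = cube.band("nir1")
    water = cube.water.copy()
    thresholds: dict = {}
    etas: list[float] = []
    if mode == "daily":
        for t in range(len(cube.dates)):
            good = cube.qa_good[t]
            vals = nir1[t][good]
            if vals.size < 2 or vals.min() == vals.max():
                continue
            thr = water_threshold(vals)
            etas.append(_separability(vals, thr))
            water[t] |= good & (nir1[t] < thr)
            thresholds[str(cube.dates[t].date())] = thr
    elif mode == "monthly_composite":
        periods = cube.dates.to_period("M")
        for per in periods.unique():
            sel = np.asarray(periods == per)
            vals = np.where(cube.qa_good[sel], nir1[sel], np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                composite = np.nanmean(vals, axis=0)
            finite = np.isfinite(composite)
            if finite.sum() < 2 or np.nanmin(composite) == np.nanmax(composite):
                continue
            thr = water_threshold(composite[finite])
            etas.append(_separability(composite[finite], thr))
            month_water = finite & (composite < thr)
            water[sel] |= month_water[None, :, :]
            thresholds[str(per)] = thr
    else:
        raise ValueError(f"unknown mode {mode!r}")

    frac = float(water.sum() / water.size)
    mean_eta = float(np.mean(etas)) if etas else 0.0
    if etas and mean_eta < min_separability:
        warnings.warn(
            f"NIR1 histogram looks unimodal (separability {mean_eta:.2f}); "
            f"no distinct water class — masked fraction {100 * frac:.2f}%")
    elif frac < min_water_frac:
        warnings.warn(f"water mask covers only {100 * frac:.2f}% of pixel-days")
    logger.info("mask_water(%s): masked fraction %.3f", mode, frac)
    return replace(cube, water=water), {"thresholds": thresholds, "masked_fraction": frac,
                                        "separability": mean_eta}


def sample_covariates(obs: pd.DataFrame, cube: ReflectanceCube) -> pd.DataFrame:
    """Attach the 7 reflectance bands to each flux observation.

    Rows whose (pixel, date) reflectance is QA- or water-masked, or whose date
    falls outside the cube, are dropped; the retention fraction is logged.
    """
    if obs.empty:
        return obs.assign(**{b: pd.Series(dtype=float) for b in cube.bands})
    dates = pd.to_datetime(obs["date"])
    t_idx = cube.dates.get_indexer(dates)
    in_range = t_idx >= 0
    if (~in_range).sum():
        warnings.warn(f"{int((~in_range).sum())} observations dated outside the cube were dropped")
    r = obs["pixel_row"].to_numpy()
    c = obs["pixel_col"].to_numpy()
    ok = in_range.copy()
    ok[in_range] &= cube.valid[t_idx[in_range], r[in_range], c[in_range]]
    out = obs[ok].copy()
    ti, ri, ci = t_idx[ok], r[ok], c[ok]
    for bi, band in enumerate(cube.bands):
        out[band] = cube.values[ti, bi, ri, ci]
    retention = len(out) / len(obs)
    logger.info("sample_covariates: retained %d/%d rows (%.1f%%)",
                len(out), len(obs), 100 * retention)
    out.attrs["retention"] = retention
    return out.reset_index(drop=True)
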