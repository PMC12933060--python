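"""Bootstrap random-forest ensemble upscaling of daily fluxes.

Maps the 7 reflectance bands to daily CO2 or CH4 flux with: a deterministic
80/20 train/holdout split stratified by observation source, k-fold
cross-validated grid search minimizing RMSE, a bootstrap ensemble (default
100 members, each fit on a with-replacement resample of the training rows)
whose across-member n-1 SD is the prediction uncertainty, and evaluation of
r^2 / RMSE / MAE at daily, monthly, seasonal and annual aggregation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .synth import BANDS, ReflectanceCube

# Documented default search grid; the CV procedure, not the grid, is the
# fixed part of the protocol.
DEFAULT_GRID = {"n_trees": [100, 300], "mtry": [2, 3, 5], "min_leaf": [1, 5, 20]}

WET_MONTHS = (5, 6, 7, 8, 9, 10)  # May-October wet season


@dataclass
class HyperParams:
    n_trees: int = 100
    mtry: int = 3
    min_leaf: int = 5
    max_depth: int | None = None


@dataclass
class EnsembleModel:
    gas: str
    members: list
    hyperparams: HyperParams
    bands: list = field(default_factory=lambda: list(BANDS))
    train_fraction: float = 0.8
    seed: int = 0

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class EvalReport:
    timescale: str
    r2: float        # squared Pearson correlation against the 1:1 line
    r2_sse: float    # 1 - SSE/SST variant
    rmse: float
    mae: float
    n: int


def split_train_holdout(rows: pd.DataFrame, train_frac: float = 0.8,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/holdout split stratified by observation source."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    train_idx = []
    for _, sub in rows.groupby("source"):
        idx = sub.index.to_numpy()
        perm = rng.permutation(len(idx))
        n_train = int(round(train_frac * len(idx)))
        train_idx.append(idx[perm[:n_train]])
    train_idx = np.concatenate(train_idx) if train_idx else np.array([], dtype=int)
    mask = rows.index.isin(train_idx)
    return rows[mask], rows[~mask]


def _make_rf(hp: HyperParams, random_state: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=hp.n_trees,
        max_features=hp.mtry,
        min_samples_leaf=hp.min_leaf,
        max_depth=hp.max_depth,
        random_state=random_state,
        n_jobs=1,
    )


def tune(X: np.ndarray, y: np.ndarray, grid: dict | None = None, k: int = 10,
         seed: int = 0) -> tuple[HyperParams, pd.DataFrame]:
    """Grid search minimizing mean k-fold CV RMSE.

    Fold assignment is deterministic given the seed; ties break toward the
    earlier grid combination.  Returns the winning HyperParams and the full
    CV table.
    """
    grid = dict(DEFAULT_GRID) if grid is None else grid
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < k:
        raise ValueError(f"need at least k={k} rows to cross-validate, got {len(y)}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    folds = list(kf.split(X))
    records = []
    combos = list(itertools.product(grid["n_trees"], grid["mtry"], grid["min_leaf"]))
    for n_trees, mtry, min_leaf in combos:
        hp = HyperParams(n_trees=n_trees, mtry=min(mtry, X.shape[1]), min_leaf=min_leaf)
        sse, n_obs = 0.0, 0
        for fold_i, (tr, te) in enumerate(folds):
            rf = _make_rf(hp, random_state=(seed + 7 * fold_i) % (2**31))
            rf.fit(X[tr], y[tr])
            resid = rf.predict(X[te]) - y[te]
            sse += float(resid @ resid)
            n_obs += len(te)
        records.append({"n_trees": n_trees, "mtry": mtry, "min_leaf": min_leaf,
                        "cv_rmse": np.sqrt(sse / n_obs)})
    table = pd.DataFrame(records)
    best = int(table["cv_rmse"].to_numpy().argmin())
    row = table.iloc[best]
    return HyperParams(n_trees=int(row["n_trees"]), mtry=int(row["mtry"]),
                       min_leaf=int(row["min_leaf"])), table


def fit_ensemble(X: np.ndarray, y: np.ndarray, hp: HyperParams, gas: str = "CO2",
                 n_members: int = 100, seed: int = 0,
                 bands: list | None = None) -> EnsembleModel:
    """Fit the bootstrap ensemble: each member trains on a with-replacement
    resample of the rows, the same size as the training set."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 training rows")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    members = []
    n = len(y)
    for _ in range(n_members):
        idx = rng.integers(0, n, size=n)
        rf = _make_rf(hp, random_state=int(rng.integers(2**31)))
        rf.fit(X[idx], y[idx])
        members.append(rf)
    return EnsembleModel(gas=gas, members=members, hyperparams=hp,
                         bands=list(BANDS) if bands is None else list(bands), seed=seed)


def predict_members(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """(n_members, n_rows) member predictions."""
    X = np.asarray(X, dtype=float)
    return np.stack([m.predict(X) for m in model.members])


def predict(model: EnsembleModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble mean and across-member n-1 SD (zero for a single member)."""
    preds = predict_members(model, X)
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0, ddof=1) if len(model.members) > 1 else np.zeros_like(mean)
    return mean, sd


def predict_grid(model: EnsembleModel, cube: ReflectanceCube,
                 date_stride: int = 1) -> dict:
    """Predict flux over all valid pixel-days (optionally every Nth day).

    Returns {"dates", "mean", "sd", "valid"} with (time, y, x) arrays; masked
    pixel-days carry NaN.
    """
    band_idx = [cube.band_index(b) for b in model.bands]
    t_sel = np.arange(0, len(cube.dates), date_stride)
    n_t = len(t_sel)
    _, _, n_r, n_c = cube.values.shape
    mean = np.full((n_t, n_r, n_c), np.nan)
    sd = np.full((n_t, n_r, n_c), np.nan)
    valid = cube.valid[t_sel]
    ti, ri, ci = np.nonzero(valid)
    if len(ti):
        X = np.stack([cube.values[t_sel[ti], b, ri, ci] for b in band_idx], axis=1)
        mu, sig = predict(model, X)
        mean[ti, ri, ci] = mu
        sd[ti, ri, ci] = sig
    return {"dates": cube.dates[t_sel], "mean": mean, "sd": sd, "valid": valid}


def member_annual_means(model: EnsembleModel, cube: ReflectanceCube,
                        date_stride: int = 1, min_coverage: float = 0.0) -> dict:
    """Per-member annual-mean flux grids.

    For each calendar year, each member's predictions are averaged over the
    sampled valid days per pixel, preserving within-member spatial covariance
    for downstream unit aggregation.  Pixels with fewer than
    ``min_coverage`` x (sampled days) valid days in a year are NaN.
    Returns {year: (n_members, y, x)}.
    """
    band_idx = [cube.band_index(b) for b in model.bands]
    t_sel = np.arange(0, len(cube.dates), date_stride)
    years = cube.dates[t_sel].year
    valid = cube.valid[t_sel]
    ti, ri, ci = np.nonzero(valid)
    X = np.stack([cube.values[t_sel[ti], b, ri, ci] for b in band_idx], axis=1)
    preds = predict_members(model, X)  # (members, n_cells)
    _, n_r, n_c = valid.shape
    out = {}
    for year in np.unique(years):
        in_year = years[ti] == year
        n_days_year = int((years == year).sum())
        counts = np.zeros((n_r, n_c))
        np.add.at(counts, (ri[in_year], ci[in_year]), 1.0)
        sums = np.zeros((model.n_members, n_r, n_c))
        for m in range(model.n_members):
            np.add.at(sums[m], (ri[in_year], ci[in_year]), preds[m, in_year])
        with np.errstate(invalid="ignore", divide="ignore"):
            annual = sums / counts[None]
        annual[:, counts < max(min_coverage * n_days_year, 1)] = np.nan
        out[int(year)] = annual
    return out


def _season_key(dates: pd.Series) -> pd.DataFrame:
    """Wet (May-Oct) vs dry season labels; Nov-Dec belong to the next
    calendar year's dry season so each season is a contiguous block."""
    d = pd.to_datetime(dates)
    wet = d.dt.month.isin(WET_MONTHS)
    season = np.where(wet, "wet", "dry")
    year = d.dt.year + ((~wet) & (d.dt.month >= 11)).astype(int)
    return pd.DataFrame({"season_year": year, "season": season})


def evaluate(paired: pd.DataFrame, timescale: str = "daily") -> EvalReport:
    """Score predictions against observations at a given aggregation.

    ``paired`` needs columns pixel_row, pixel_col, date, obs, pred.  For
    monthly/seasonal/annual, obs and pred are first averaged within
    (pixel x period); r^2 is the squared Pearson correlation (1:1 validation
    style), with the 1-SSE/SST variant also reported.
    """
    if paired.empty:
        raise ValueError("no overlapping observation/prediction pairs")
    df = paired.copy()
    d = pd.to_datetime(df["date"])
    if timescale == "daily":
        grouped = df
    else:
        if timescale == "monthly":
            df["_p1"], df["_p2"] = d.dt.year, d.dt.month
        elif timescale == "seasonal":
            sk = _season_key(df["date"])
            df["_p1"], df["_p2"] = sk["season_year"].values, sk["season"].values
        elif timescale == "annual":
            df["_p1"], df["_p2"] = d.dt.year, 0
        else:
            raise ValueError(f"unknown timescale {timescale!r}")
        grouped = df.groupby(["pixel_row", "pixel_col", "_p1", "_p2"], as_index=False)[
            ["obs", "pred"]].mean()
    obs = grouped["obs"].to_numpy(dtype=float)
    pred = grouped["pred"].to_numpy(dtype=float)
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if len(obs) > 1 and obs.std() > 0 and pred.std() > 0:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        r2 = np.nan
    sst = float(((obs - obs.mean()) ** 2).sum())
    r2_sse = float(1.0 - (resid @ resid) / sst) if sst > 0 else np.nan
    return EvalReport(timescale=timescale, r2=r2, r2_sse=r2_sse, rmse=rmse,
                      mae=mae, n=len(obs))


def evaluate_holdout(model: EnsembleModel, holdout: pd.DataFrame,
                     timescales=("daily", "monthly", "seasonal", "annual")) -> pd.DataFrame:
    """Predict the held-out covariate rows and score at each timescale."""
    X = holdout[model.bands].to_numpy(dtype=float)
    mu, _ = predict(model, X)
    paired = holdout[["pixel_row", "pixel_col", "date"]].copy()
    paired["obs"] = holdout["mean"].to_numpy(dtype=float)
    paired["pred"] = mu
    reports = [evaluate(paired, ts) for ts in timescales]
    return pd.DataFrame([r.__dict__ for r in reports])
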