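"""Readers and writers for the pipeline's on-disk formats.

Grids travel as NetCDF (via xarray's scipy backend), label rasters as TIFF
with a JSON sidecar carrying the affine georeference, tables as CSV, and
configuration as YAML.  Writers refuse unitless flux arrays; the NetCDF
reader reorders bands to the canonical order by name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from .synth import BANDS, PIXEL_SIZE_M, ReflectanceCube


def write_cube(cube: ReflectanceCube, path) -> None:
    ds = xr.Dataset(
        {
            "reflectance": (("time", "band", "y", "x"), cube.values),
            "qa_good": (("time", "y", "x"), cube.qa_good.astype(np.int8)),
            "water": (("time", "y", "x"), cube.water.astype(np.int8)),
        },
        coords={"time": cube.dates, "band": cube.bands},
        attrs={"units": "reflectance [0,1]", "pixel_size_m": PIXEL_SIZE_M,
               "conventions": "0-based row-major pixel indices, pixel-center registration"},
    )
    ds.to_netcdf(path, engine="scipy")


def read_cube(path) -> ReflectanceCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    names = [str(b) for b in ds["band"].values]
    if sorted(names) != sorted(BANDS):
        raise ValueError(f"unexpected band set {names}")
    order = [names.index(b) for b in BANDS]
    return ReflectanceCube(
        values=ds["reflectance"].values[:, order],
        dates=pd.DatetimeIndex(ds["time"].values),
        bands=list(BANDS),
        qa_good=ds["qa_good"].values.astype(bool),
        water=ds["water"].values.astype(bool),
    )


def write_flux_grid(mean: np.ndarray, sd: np.ndarray, dates, gas: str,
                    units: str, path) -> None:
    """Predicted flux grid (mean + ensemble SD) to NetCDF; units required."""
    if not units:
        raise ValueError("refusing to write a unitless flux grid")
    ds = xr.Dataset(
        {"mean": (("time", "y", "x"), np.asarray(mean)),
         "sd": (("time", "y", "x"), np.asarray(sd))},
        coords={"time": pd.DatetimeIndex(dates)},
        attrs={"gas": gas, "units": units, "pixel_size_m": PIXEL_SIZE_M},
    )
    ds.to_netcdf(path, engine="scipy")


def read_flux_grid(path) -> dict:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    return {"mean": ds["mean"].values, "sd": ds["sd"].values,
            "dates": pd.DatetimeIndex(ds["time"].values),
            "gas": ds.attrs.get("gas"), "units": ds.attrs.get("units")}


def write_labels(labels: np.ndarray, path, classes: list | None = None) -> None:
    """Label raster as TIFF + JSON sidecar with georeference metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
    sidecar = {"pixel_size_m": PIXEL_SIZE_M, "origin": [0, 0],
               "registration": "pixel-center", "classes": classes}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_labels(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = {}
    if path.with_suffix(".json").exists():
        sidecar = json.loads(path.with_suffix(".json").read_text())
    return labels, sidecar


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, required_columns=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required_columns:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
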