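"""Synthetic wetland landscape generator.

Emulates the data structure of a multiscale greenhouse-gas flux study over a
tidal-to-freshwater wetland gradient: a habitat mosaic on a 500-m grid, daily
7-band surface reflectance with seasonal cycles, disturbance pulses and QA
dropout, habitat-dependent flux-reflectance relations with known coefficients
(strong CO2 uptake in mangrove, high CH4 in freshwater marsh), half-hourly
tower time series with an affine midday-to-daily CO2 relation built in, and
midday airborne flux transects.  Every output is deterministic for a fixed
seed, so downstream stages can be tested against known ground truth.

Units follow field convention: CO2 fluxes in umol m-2 s-1 (negative = uptake),
CH4 fluxes in nmol m-2 s-1.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

HABITATS = ["mangrove", "saltmarsh", "freshwater_marsh", "swamp", "upland", "water"]
BANDS = ["blue", "green", "red", "nir1", "nir2", "swir1", "swir2"]

# Fraction of the landscape per habitat (mosaic broadly inspired by a
# mangrove/marsh/swamp wetland complex with some upland and open water).
DEFAULT_FRACTIONS = {
    "mangrove": 0.20,
    "saltmarsh": 0.10,
    "freshwater_marsh": 0.30,
    "swamp": 0.15,
    "upland": 0.10,
    "water": 0.15,
}

# Ordering of classes along the coastal->inland gradient used when carving the
# smoothed random field into patches (water = open coastal water first).
_GRADIENT_ORDER = ["water", "mangrove", "saltmarsh", "swamp", "freshwater_marsh", "upland"]

# Baseline 7-band reflectance per habitat.  Water is dark in the NIR (0.03,
# below every land baseline) so histogram water masking is well posed.
BASE_SPECTRA = {
    "mangrove":         [0.03, 0.06, 0.04, 0.35, 0.30, 0.15, 0.08],
    "saltmarsh":        [0.04, 0.08, 0.07, 0.28, 0.26, 0.20, 0.12],
    "freshwater_marsh": [0.04, 0.07, 0.06, 0.30, 0.28, 0.18, 0.10],
    "swamp":            [0.03, 0.06, 0.05, 0.32, 0.28, 0.16, 0.09],
    "upland":           [0.05, 0.09, 0.08, 0.26, 0.25, 0.22, 0.14],
    "water":            [0.02, 0.03, 0.02, 0.03, 0.02, 0.01, 0.01],
}

# Annual-cycle amplitude per band (added as amp * cos(2*pi*(t - peak)/365.25);
# greenness peaks in the wet season, SWIR dips as the surface wets up).
SEASONAL_AMP = {
    "mangrove":         [0.002, 0.005, 0.003, 0.030, 0.025, -0.010, -0.008],
    "saltmarsh":        [0.003, 0.006, 0.004, 0.035, 0.030, -0.020, -0.012],
    "freshwater_marsh": [0.005, 0.010, 0.005, 0.050, 0.040, -0.030, -0.020],
    "swamp":            [0.003, 0.006, 0.004, 0.040, 0.030, -0.015, -0.010],
    "upland":           [0.002, 0.004, 0.003, 0.020, 0.018, -0.008, -0.005],
    "water":            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
}

# Daily CO2 flux = alpha + beta * NIR1 (+ noise): greener canopy -> stronger
# uptake.  Coefficients set so habitat means at baseline reflectance are
# mangrove -4.0 < swamp -3.0 < saltmarsh -2.5 < freshwater marsh -2.0 <
# upland -1.5 umol m-2 s-1, with water neutral.
CO2_COEF = {
    "mangrove": (6.5, -30.0),
    "saltmarsh": (5.9, -30.0),
    "freshwater_marsh": (7.0, -30.0),
    "swamp": (6.6, -30.0),
    "upland": (6.3, -30.0),
    "water": (0.0, 0.0),
}

# Daily CH4 flux = gamma + delta * (NIR1 - SWIR1): the NIR-SWIR difference is
# the wetness proxy.  Habitat means at baseline: freshwater marsh 150 >>
# swamp 60 > saltmarsh 40 > mangrove 25 > water 10 > upland 5 nmol m-2 s-1.
CH4_COEF = {
    "mangrove": (13.0, 60.0),
    "saltmarsh": (35.2, 60.0),
    "freshwater_marsh": (102.0, 400.0),
    "swamp": (36.0, 150.0),
    "upland": (4.2, 20.0),
    "water": (10.0, 0.0),
}

_EPOCH = dt.date(2000, 1, 1)
# days from epoch to the wet-season greenness peak (~Aug 20, 2000)
_SEASON_PEAK = 232.0
PIXEL_SIZE_M = 500.0


@dataclass
class DisturbanceEvent:
    """A pulse disturbance (hurricane or fire) with linear recovery."""

    date: dt.date
    center: tuple[int, int]
    radius: float  # pixels
    reflectance_shock: float = 0.5  # fractional NIR loss at day 0
    recovery_days: int = 730
    kind: str = "hurricane"


@dataclass
class LandscapeConfig:
    n_rows: int = 40
    n_cols: int = 40
    start_date: dt.date = dt.date(2021, 1, 1)
    end_date: dt.date = dt.date(2023, 12, 31)
    habitat_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    patch_smoothness: float = 3.0
    seed: int = 0
    qa_dropout_frac: float = 0.36
    disturbance_events: list = field(default_factory=list)
    coastal_gradient: float = 1.5  # strength of the west->east habitat gradient
    reflectance_noise_sd: float = 0.01
    co2_noise_sd: float = 0.6   # umol m-2 s-1, process noise on daily CO2
    ch4_noise_sd: float = 18.0  # nmol m-2 s-1, process noise on daily CH4

    def __post_init__(self):
        total = sum(self.habitat_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"habitat fractions sum to {total}, expected 1")
        unknown = set(self.habitat_fractions) - set(HABITATS)
        if unknown:
            raise ValueError(f"unknown habitat classes: {sorted(unknown)}")
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")
        if not 0.0 <= self.qa_dropout_frac < 1.0:
            raise ValueError("qa_dropout_frac must be in [0, 1)")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, self.end_date, freq="D")


@dataclass
class HabitatMap:
    labels: np.ndarray  # (n_rows, n_cols) int, index into HABITATS
    classes: list = field(default_factory=lambda: list(HABITATS))

    def fraction(self, habitat: str) -> float:
        return float(np.mean(self.labels == self.classes.index(habitat)))

    def mask(self, habitat: str) -> np.ndarray:
        return self.labels == self.classes.index(habitat)


@dataclass
class ReflectanceCube:
    """Daily 7-band reflectance with QA and water masks.

    values has shape (time, band, y, x); qa_good and water are (time, y, x).
    A cell participates in training/prediction only where ``valid`` is True.
    """

    values: np.ndarray
    dates: pd.DatetimeIndex
    bands: list
    qa_good: np.ndarray
    water: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.qa_good & ~self.water

    def band_index(self, name: str) -> int:
        return self.bands.index(name)

    def band(self, name: str) -> np.ndarray:
        return self.values[:, self.band_index(name)]


@dataclass
class TrueFluxField:
    co2_daily: np.ndarray  # (time, y, x) umol m-2 s-1
    ch4_daily: np.ndarray  # (time, y, x) nmol m-2 s-1
    dates: pd.DatetimeIndex
    generator_params: dict


@dataclass
class DielProfile:
    """Parameters of the built-in diel cycle of tower CO2 flux.

    The half-hourly series is constructed so that, at amplitude 1 and zero
    noise, daily mean = a_true * midday mean + b_true holds exactly, i.e. an
    affine midday-to-daily relation is recoverable by ordinary regression.
    """

    a_true: float = 0.27
    b_true: float = 0.58
    amplitude: float = 1.0
    noise_sd: float = 1.5       # half-hourly CO2 noise, umol m-2 s-1
    ch4_noise_sd: float = 30.0  # half-hourly CH4 noise, nmol m-2 s-1

    def __post_init__(self):
        if self.a_true <= 0:
            raise ValueError("a_true must be positive")


@dataclass
class FlightSpec:
    """One straight midday transect along a grid row."""

    date: dt.date
    row: int
    col_start: int = 0
    col_end: int | None = None  # exclusive; None = full width
    start_time: dt.time = dt.time(10, 30)
    speed_ms: float = 100.0


def _rng(config: LandscapeConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_habitat_map(config: LandscapeConfig) -> HabitatMap:
    """Carve a smoothed random field into contiguous habitat patches.

    A Gaussian-smoothed noise field plus a west-east gradient is thresholded
    at the cumulative class-fraction quantiles, which realizes the requested
    fractions exactly up to ties while keeping patches spatially contiguous
    and ordering classes coastal (water, mangrove) to inland (upland).
    """
    rng = _rng(config, 0)
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    fld = ndimage.gaussian_filter(noise, sigma=config.patch_smoothness)
    sd = fld.std()
    if sd > 0:
        fld = fld / sd
    cols = np.arange(config.n_cols) / max(config.n_cols - 1, 1)
    fld = fld + config.coastal_gradient * cols[None, :]

    order = [h for h in _GRADIENT_ORDER if config.habitat_fractions.get(h, 0) > 0]
    fracs = np.array([config.habitat_fractions[h] for h in order])
    cum = np.cumsum(fracs)[:-1]
    thresholds = np.quantile(fld, cum) if len(cum) else np.array([])
    idx = np.searchsorted(thresholds, fld, side="right")
    labels = np.empty(fld.shape, dtype=np.int64)
    for i, h in enumerate(order):
        labels[idx == i] = HABITATS.index(h)
    return HabitatMap(labels=labels)


def _seasonal_phase(dates: pd.DatetimeIndex) -> np.ndarray:
    t = (dates - pd.Timestamp(_EPOCH)) / pd.Timedelta(days=1)
    return np.cos(2.0 * np.pi * (np.asarray(t, dtype=float) - _SEASON_PEAK) / 365.25)


def simulate_reflectance(hab_map: HabitatMap, config: LandscapeConfig) -> ReflectanceCube:
    """Daily 7-band reflectance: habitat baseline + annual cosine + disturbance
    shocks with linear recovery + i.i.d. noise, plus a random QA dropout mask."""
    if hab_map.labels.shape != (config.n_rows, config.n_cols):
        raise ValueError("habitat map dimensions do not match config")
    dates = config.dates
    n_t = len(dates)
    labels = hab_map.labels

    base = np.array([BASE_SPECTRA[h] for h in HABITATS])      # (class, band)
    amp = np.array([SEASONAL_AMP[h] for h in HABITATS])
    base_px = base[labels]                                     # (y, x, band)
    amp_px = amp[labels]
    phase = _seasonal_phase(dates)                             # (time,)

    values = (
        base_px[None, :, :, :] + phase[:, None, None, None] * amp_px[None, :, :, :]
    ).transpose(0, 3, 1, 2).astype(np.float64)                 # (t, band, y, x)

    # disturbance pulses: NIR collapse with linear recovery, slight red/SWIR rise
    nir = [BANDS.index("nir1"), BANDS.index("nir2")]
    bright = [BANDS.index("red"), BANDS.index("swir1"), BANDS.index("swir2")]
    rows, cols_idx = np.indices(labels.shape)
    day_num = np.array([(d.date() - _EPOCH).days for d in dates])
    for ev in config.disturbance_events:
        dist = np.hypot(rows - ev.center[0], cols_idx - ev.center[1])
        inside = dist <= ev.radius
        if not inside.any():
            continue
        ddays = day_num - (ev.date - _EPOCH).days
        factor = ev.reflectance_shock * np.clip(1.0 - ddays / max(ev.recovery_days, 1), 0.0, 1.0)
        factor[ddays < 0] = 0.0
        for b in nir:
            values[:, b][:, inside] *= (1.0 - factor[:, None])
        for b in bright:
            values[:, b][:, inside] *= (1.0 + 0.3 * factor[:, None])

    if config.reflectance_noise_sd > 0:
        rng = _rng(config, 1)
        values = values + rng.normal(0.0, config.reflectance_noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    qa_rng = _rng(config, 2)
    qa_good = qa_rng.random((n_t, config.n_rows, config.n_cols)) >= config.qa_dropout_frac
    water = np.zeros_like(qa_good)
    return ReflectanceCube(values=values, dates=dates, bands=list(BANDS),
                           qa_good=qa_good, water=water)


def simulate_true_fluxes(cube: ReflectanceCube, hab_map: HabitatMap,
                         config: LandscapeConfig) -> TrueFluxField:
    """True daily fluxes as habitat-specific functions of the reflectance cube.

    CO2 is affine in NIR1 per habitat; CH4 is affine in the NIR1-SWIR1
    wetness proxy.  Gaussian process noise (config.co2_noise_sd /
    ch4_noise_sd) is added on top of the deterministic part.
    """
    labels = hab_map.labels
    nir1 = cube.band("nir1")
    swir1 = cube.band("swir1")
    co2_a = np.array([CO2_COEF[h][0] for h in HABITATS])[labels]
    co2_b = np.array([CO2_COEF[h][1] for h in HABITATS])[labels]
    ch4_a = np.array([CH4_COEF[h][0] for h in HABITATS])[labels]
    ch4_b = np.array([CH4_COEF[h][1] for h in HABITATS])[labels]

    co2 = co2_a[None] + co2_b[None] * nir1
    ch4 = ch4_a[None] + ch4_b[None] * (nir1 - swir1)
    rng = _rng(config, 3)
    if config.co2_noise_sd > 0:
        co2 = co2 + rng.normal(0.0, config.co2_noise_sd, size=co2.shape)
    if config.ch4_noise_sd > 0:
        ch4 = ch4 + rng.normal(0.0, config.ch4_noise_sd, size=ch4.shape)
    return TrueFluxField(
        co2_daily=co2, ch4_daily=ch4, dates=cube.dates,
        generator_params={"co2": dict(CO2_COEF), "ch4": dict(CH4_COEF)},
    )


# ---------------------------------------------------------------------------
# diel machinery

_HALF_HOURS = (np.arange(48) + 0.5) / 2.0  # half-hour midpoints, 0.25..23.75 h
MIDDAY_WINDOW = (10.0, 14.0)


def _diel_shape() -> np.ndarray:
    """Zero-daily-mean diel modulation: half-sinusoid drawdown 06:00-18:00."""
    s = np.where(
        (_HALF_HOURS >= 6.0) & (_HALF_HOURS < 18.0),
        -np.sin(np.pi * (_HALF_HOURS - 6.0) / 12.0),
        0.0,
    )
    return s - s.mean()


_SHAPE = _diel_shape()
_MID = (_HALF_HOURS >= MIDDAY_WINDOW[0]) & (_HALF_HOURS < MIDDAY_WINDOW[1])
_S_MID = _SHAPE[_MID].mean()


def simulate_tower(pixel: tuple[int, int], dates: pd.DatetimeIndex,
                   flux_field: TrueFluxField, profile: DielProfile,
                   gap_rate: float = 0.0, tower_id: str = "T0",
                   seed: int = 0) -> pd.DataFrame:
    """Half-hourly tower series (48 records/day/gas) at one pixel.

    CO2 gets the diel modulation scaled so the daily mean equals the field
    value and, at amplitude 1, midday and daily means obey the profile's
    affine relation exactly when noise_sd = 0.  CH4 is flat through the day.
    Random gaps are inserted at gap_rate.
    """
    r, c = pixel
    if not (0 <= r < flux_field.co2_daily.shape[1] and 0 <= c < flux_field.co2_daily.shape[2]):
        raise ValueError(f"pixel {pixel} outside grid")
    date_pos = flux_field.dates.get_indexer(dates)
    if (date_pos < 0).any():
        raise ValueError("requested dates outside flux field range")
    m_co2 = flux_field.co2_daily[date_pos, r, c]  # (n_days,)
    m_ch4 = flux_field.ch4_daily[date_pos, r, c]

    a, b = profile.a_true, profile.b_true
    if abs(1.0 - a) < 1e-12:
        coef_a, m0 = 0.0, 0.0  # slope 1: no modulation scaling possible
    else:
        coef_a = (1.0 / a - 1.0) / _S_MID
        m0 = b / (1.0 - a)

    rng = np.random.default_rng(np.random.SeedSequence([seed, r, c]))
    n_days = len(dates)
    co2 = m_co2[:, None] + profile.amplitude * coef_a * (m_co2 - m0)[:, None] * _SHAPE[None, :]
    ch4 = np.broadcast_to(m_ch4[:, None], (n_days, 48)).copy()
    if profile.noise_sd > 0:
        co2 = co2 + rng.normal(0.0, profile.noise_sd, size=co2.shape)
    if profile.ch4_noise_sd > 0:
        ch4 = ch4 + rng.normal(0.0, profile.ch4_noise_sd, size=ch4.shape)

    base = pd.to_datetime(dates).values[:, None]
    ts = (base + (pd.to_timedelta(_HALF_HOURS, unit="h").values)[None, :]).ravel()
    keep = np.ones(n_days * 48, dtype=bool)
    if gap_rate > 0:
        keep = rng.random(n_days * 48) >= gap_rate

    frames = []
    for gas, vals in (("CO2", co2), ("CH4", ch4)):
        frames.append(pd.DataFrame({
            "tower_id": tower_id,
            "pixel_row": r, "pixel_col": c,
            "timestamp": ts[keep], "gas": gas,
            "flux": vals.ravel()[keep], "qc": 0,
        }))
    return pd.concat(frames, ignore_index=True)


def true_midday_co2(flux_field: TrueFluxField, profile: DielProfile) -> np.ndarray:
    """Invert the diel relation: midday mean implied by the daily field."""
    return (flux_field.co2_daily - profile.b_true) / profile.a_true


def simulate_flights(tracks: list[FlightSpec], flux_field: TrueFluxField,
                     profile: DielProfile, co2_noise_sd: float = 2.0,
                     ch4_noise_sd: float = 40.0, seed: int = 0) -> pd.DataFrame:
    """1-Hz airborne samples along straight row transects.

    Sample value = pixel's true midday flux plus noise; only samples whose
    timestamp falls inside the midday window [10:00, 14:00) are emitted.
    At 100 m/s and 1 Hz a 500-m pixel yields ~5 samples.
    """
    n_t, n_rows, n_cols = flux_field.co2_daily.shape
    midday_co2 = None
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    out = []
    n_outside = 0
    for track in tracks:
        c1 = n_cols if track.col_end is None else track.col_end
        if not (0 <= track.row < n_rows) or c1 <= track.col_start:
            n_outside += 1
            continue
        t_idx = flux_field.dates.get_indexer([pd.Timestamp(track.date)])[0]
        if t_idx < 0:
            n_outside += 1
            continue
        length_m = (c1 - track.col_start) * PIXEL_SIZE_M
        n_sec = int(length_m / track.speed_ms)
        secs = np.arange(n_sec)
        pos_m = track.col_start * PIXEL_SIZE_M + track.speed_ms * (secs + 0.5)
        cols = np.minimum((pos_m // PIXEL_SIZE_M).astype(int), n_cols - 1)
        t0 = dt.datetime.combine(track.date, track.start_time)
        stamps = pd.Timestamp(t0) + pd.to_timedelta(secs, unit="s")
        hours = stamps.hour + stamps.minute / 60.0 + stamps.second / 3600.0
        in_window = (hours >= MIDDAY_WINDOW[0]) & (hours < MIDDAY_WINDOW[1])
        if not in_window.any():
            continue
        if midday_co2 is None:
            midday_co2 = true_midday_co2(flux_field, profile)
        co2_true = midday_co2[t_idx, track.row, cols]
        ch4_true = flux_field.ch4_daily[t_idx, track.row, cols]
        co2 = co2_true + (rng.normal(0.0, co2_noise_sd, size=co2_true.shape)
                          if co2_noise_sd > 0 else 0.0)
        ch4 = ch4_true + (rng.normal(0.0, ch4_noise_sd, size=ch4_true.shape)
                          if ch4_noise_sd > 0 else 0.0)
        for gas, vals in (("CO2", co2), ("CH4", ch4)):
            out.append(pd.DataFrame({
                "timestamp": stamps[in_window], "pixel_row": track.row,
                "pixel_col": cols[in_window], "gas": gas, "flux": vals[in_window],
            }))
    if n_outside:
        import warnings
        warnings.warn(f"{n_outside} track(s) outside the grid or date range")
    if not out:
        return pd.DataFrame(columns=["timestamp", "pixel_row", "pixel_col", "gas", "flux"])
    return pd.concat(out, ignore_index=True)


def generate_unit_map(config: LandscapeConfig, n_unit_rows: int = 4,
                      n_unit_cols: int = 4) -> np.ndarray:
    """Rectangular management-unit partition of the grid (labels 0..n-1)."""
    r = np.minimum(np.arange(config.n_rows) * n_unit_rows // config.n_rows, n_unit_rows - 1)
    c = np.minimum(np.arange(config.n_cols) * n_unit_cols // config.n_cols, n_unit_cols - 1)
    return (r[:, None] * n_unit_cols + c[None, :]).astype(np.int64)


def disturbance_footprints(config: LandscapeConfig) -> dict:
    """Boolean footprint per disturbance kind (union over events)."""
    rows, cols = np.indices((config.n_rows, config.n_cols))
    out: dict[str, np.ndarray] = {}
    for ev in config.disturbance_events:
        inside = np.hypot(rows - ev.center[0], cols - ev.center[1]) <= ev.radius
        out[ev.kind] = out.get(ev.kind, np.zeros_like(inside)) | inside
    return out


def place_towers(hab_map: HabitatMap, wanted: list[str] | None = None) -> list[dict]:
    """Deterministically place towers in representative habitat pixels.

    Default network mirrors an 8-tower layout: 2 mangrove, 2 freshwater
    marsh, 1 saltmarsh, 2 swamp, 1 upland.
    """
    if wanted is None:
        wanted = ["mangrove", "mangrove", "freshwater_marsh", "freshwater_marsh",
                  "saltmarsh", "swamp", "swamp", "upland"]
    towers = []
    counts: dict[str, int] = {}
    for i, hab in enumerate(wanted):
        pix = np.argwhere(hab_map.mask(hab))
        if len(pix) == 0:
            continue
        k = counts.get(hab, 0)
        counts[hab] = k + 1
        # spread multiple towers of the same habitat across its patch list
        j = (len(pix) * (2 * k + 1)) // (2 * max(counts[hab], wanted.count(hab)))
        r, c = pix[min(j, len(pix) - 1)]
        towers.append({"tower_id": f"T{i}", "habitat": hab, "pixel": (int(r), int(c))})
    return towers
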