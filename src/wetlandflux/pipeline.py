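"""End-to-end orchestration: simulate -> ingest -> covariates -> train ->
predict -> account -> trend -> attribute, under one seeded configuration.

``run_all`` executes every stage on a single PipelineConfig, returns the
in-memory artifacts, and (optionally) writes tables plus a manifest with
per-stage checksums so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accounting, attribution, ingest, reflectance, upscaler
from . import synth
from .accounting import AccountingConfig
from .ingest import DielConversion
from .synth import DielProfile, DisturbanceEvent, FlightSpec, LandscapeConfig

logger = logging.getLogger(__name__)

DEFAULT_PATH_SPEC = [
    ("dist_to_shore", "pct_mangrove"),
    ("pct_mangrove", "pct_ghost_forest"),
    ("pct_ghost_forest", "mean_co2"),
    ("pct_mangrove", "mean_co2"),
    ("pct_freshwater_marsh", "mean_co2"),
    ("pct_freshwater_marsh", "mean_ch4"),
]

PCA_VARIABLES = [
    "mean_co2", "mean_ch4", "pct_mangrove", "pct_saltmarsh",
    "pct_freshwater_marsh", "pct_swamp", "pct_upland", "pct_water",
    "pct_ghost_forest", "pct_burned", "dist_to_shore",
]


@dataclass
class ModelConfig:
    grid: dict = field(default_factory=lambda: dict(upscaler.DEFAULT_GRID))
    cv_k: int = 10
    train_frac: float = 0.8
    n_members: int = 100
    date_stride: int = 1
    refit_full: bool = False  # False: production grids come from the 80% fit


@dataclass
class PipelineConfig:
    scenario: LandscapeConfig = field(default_factory=LandscapeConfig)
    diel: DielProfile = field(default_factory=DielProfile)
    model: ModelConfig = field(default_factory=ModelConfig)
    accounting: AccountingConfig = field(default_factory=AccountingConfig)
    min_coverage: float = 0.8
    gap_rate: float = 0.1
    water_mask_mode: str = "monthly_composite"
    use_fitted_conversion: bool = True
    conversion: DielConversion = field(default_factory=DielConversion)
    flight_days_per_year: int = 10
    transects_per_day: int = 4
    n_unit_rows: int = 4
    n_unit_cols: int = 4
    path_spec: list = field(default_factory=lambda: list(DEFAULT_PATH_SPEC))
    pca_threshold: float = 0.3
    seed: int = 0


def default_demo_config(seed: int = 0) -> PipelineConfig:
    """The default demonstration scenario: 40x40 pixels x 3 years, an
    ensemble of 20 members, weekly prediction sampling, and a compact tuning
    grid sized so the full pipeline runs in minutes on one CPU."""
    scenario = LandscapeConfig(
        n_rows=40, n_cols=40,
        start_date=dt.date(2021, 1, 1), end_date=dt.date(2023, 12, 31),
        seed=seed,
        disturbance_events=[
            DisturbanceEvent(date=dt.date(2022, 9, 15), center=(20, 6), radius=8.0,
                             reflectance_shock=0.4, recovery_days=730, kind="hurricane"),
            DisturbanceEvent(date=dt.date(2022, 4, 10), center=(10, 30), radius=5.0,
                             reflectance_shock=0.3, recovery_days=365, kind="fire"),
        ],
    )
    model = ModelConfig(grid={"n_trees": [100], "mtry": [2, 3], "min_leaf": [5, 20]},
                        n_members=20, date_stride=7)
    return PipelineConfig(scenario=scenario, model=model, seed=seed)


# ---------------------------------------------------------------------------
# config (de)serialization

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if isinstance(obj, dt.time):
        return obj.isoformat()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_to_dict(config: PipelineConfig) -> dict:
    return _to_jsonable(config)


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    scen = dict(d.pop("scenario"))
    scen["start_date"] = dt.date.fromisoformat(scen["start_date"])
    scen["end_date"] = dt.date.fromisoformat(scen["end_date"])
    scen["disturbance_events"] = [
        DisturbanceEvent(date=dt.date.fromisoformat(e["date"]),
                         center=tuple(e["center"]), radius=e["radius"],
                         reflectance_shock=e["reflectance_shock"],
                         recovery_days=e["recovery_days"], kind=e["kind"])
        for e in scen.get("disturbance_events", [])
    ]
    cfg = PipelineConfig(
        scenario=LandscapeConfig(**scen),
        diel=DielProfile(**d.pop("diel")),
        model=ModelConfig(**d.pop("model")),
        accounting=AccountingConfig(**d.pop("accounting")),
        conversion=DielConversion(**d.pop("conversion")),
        **{k: v for k, v in d.items() if k != "path_spec"},
    )
    if "path_spec" in d:
        cfg.path_spec = [tuple(e) for e in d["path_spec"]]
    return cfg


def _checksum(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, pd.DataFrame):
            h.update(part.to_csv(index=False).encode())
        elif isinstance(part, np.ndarray):
            h.update(np.ascontiguousarray(part).tobytes())
        else:
            h.update(json.dumps(_to_jsonable(part), sort_keys=True).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stage helpers

def plan_flights(config: PipelineConfig) -> list[FlightSpec]:
    """Deterministic midday flight plan.

    Emulates seasonal airborne deployments that re-fly a fixed set of flight
    lines: ~flight_days_per_year days spread over wet and dry seasons, each
    flying transects_per_day lines from a grid-spanning set of 2x
    transects_per_day repeated lines (alternating halves), so every line is
    revisited several times per year across seasons.
    """
    scen = config.scenario
    n_lines = 2 * config.transects_per_day
    lines = np.linspace(2, scen.n_rows - 3, n_lines).astype(int)
    specs: list[FlightSpec] = []
    years = range(scen.start_date.year, scen.end_date.year + 1)
    doys = np.linspace(20, 350, config.flight_days_per_year).astype(int)
    f = 0
    for year in years:
        for doy in doys:
            date = dt.date(year, 1, 1) + dt.timedelta(days=int(doy) - 1)
            if not (scen.start_date <= date <= scen.end_date):
                continue
            for k in range(config.transects_per_day):
                row = int(lines[(2 * k + (f % 2)) % n_lines])
                start = (dt.datetime.combine(date, dt.time(10, 30))
                         + dt.timedelta(minutes=13 * k)).time()
                specs.append(FlightSpec(date=date, row=row, start_time=start))
            f += 1
    return specs


def simulate_stage(config: PipelineConfig) -> dict:
    scen = config.scenario
    hab_map = synth.generate_habitat_map(scen)
    cube = synth.simulate_reflectance(hab_map, scen)
    truth = synth.simulate_true_fluxes(cube, hab_map, scen)
    towers = synth.place_towers(hab_map)
    tower_hh = pd.concat(
        [synth.simulate_tower(t["pixel"], cube.dates, truth, config.diel,
                              gap_rate=config.gap_rate, tower_id=t["tower_id"],
                              seed=scen.seed)
         for t in towers],
        ignore_index=True)
    flights = plan_flights(config)
    flight_samples = synth.simulate_flights(flights, truth, config.diel, seed=scen.seed)
    unit_map = synth.generate_unit_map(scen, config.n_unit_rows, config.n_unit_cols)
    return {"hab_map": hab_map, "cube": cube, "truth": truth, "towers": towers,
            "tower_hh": tower_hh, "flights": flights,
            "flight_samples": flight_samples, "unit_map": unit_map}


def ingest_stage(config: PipelineConfig, sim: dict) -> dict:
    tower_daily = ingest.daily_from_halfhourly(sim["tower_hh"], config.min_coverage)
    if config.use_fitted_conversion:
        mid = ingest.midday_means(sim["tower_hh"])
        co2_mid = mid[mid["gas"] == "CO2"]
        co2_daily = tower_daily[tower_daily["gas"] == "CO2"]
        pairs = co2_mid.merge(co2_daily, on=["pixel_row", "pixel_col", "date", "gas"])
        conv = ingest.fit_midday_daily(pairs[["midday_mean", "mean"]].to_numpy())
    else:
        conv = config.conversion
    gridded = ingest.grid_airborne(
        sim["flight_samples"], (config.scenario.n_rows, config.scenario.n_cols))
    air_daily = ingest.airborne_daily(gridded, conv)
    training = ingest.merge_observations(tower_daily, air_daily)
    return {"tower_daily": tower_daily, "conversion": conv,
            "airborne_daily": air_daily, "training": training}


def covariate_stage(config: PipelineConfig, sim: dict, ing: dict) -> dict:
    cube = reflectance.apply_qa_mask(sim["cube"])
    cube, water_report = reflectance.mask_water(cube, mode=config.water_mask_mode)
    rows = reflectance.sample_covariates(ing["training"], cube)
    return {"cube": cube, "water_report": water_report, "rows": rows,
            "retention": rows.attrs.get("retention")}


def train_stage(config: PipelineConfig, cov: dict) -> dict:
    out = {}
    for gas in ("CO2", "CH4"):
        rows = cov["rows"][cov["rows"]["gas"] == gas].reset_index(drop=True)
        train, holdout = upscaler.split_train_holdout(
            rows, config.model.train_frac, seed=config.seed)
        X = train[synth.BANDS].to_numpy(dtype=float)
        y = train["mean"].to_numpy(dtype=float)
        hp, cv_table = upscaler.tune(X, y, grid=config.model.grid,
                                     k=config.model.cv_k, seed=config.seed)
        model = upscaler.fit_ensemble(X, y, hp, gas=gas,
                                      n_members=config.model.n_members,
                                      seed=config.seed)
        evals = upscaler.evaluate_holdout(model, holdout)
        if config.model.refit_full:
            X_all = rows[synth.BANDS].to_numpy(dtype=float)
            model = upscaler.fit_ensemble(X_all, rows["mean"].to_numpy(dtype=float),
                                          hp, gas=gas,
                                          n_members=config.model.n_members,
                                          seed=config.seed)
        out[gas] = {"model": model, "hyperparams": hp, "cv_table": cv_table,
                    "evaluation": evals, "n_train": len(train), "n_holdout": len(holdout)}
    return out


def account_stage(config: PipelineConfig, sim: dict, cov: dict, trained: dict) -> dict:
    acc = config.accounting
    member_mass = {}   # gas -> {year: (members, y, x)} in g gas / pixel / y
    annual_mean_mass = {}
    for gas in ("CO2", "CH4"):
        grids = upscaler.member_annual_means(
            trained[gas]["model"], cov["cube"], date_stride=config.model.date_stride)
        scale = accounting.mass_scale(gas, acc)
        member_mass[gas] = {yr: g * scale for yr, g in grids.items()}
        with warnings.catch_warnings():
            # water/QA-masked pixels are all-NaN across members by design
            warnings.simplefilter("ignore", RuntimeWarning)
            annual_mean_mass[gas] = {yr: np.nanmean(g, axis=0)
                                     for yr, g in member_mass[gas].items()}
    years = sorted(member_mass["CO2"])

    # regional budget per year: sum members over the region, MMT
    regional = []
    for yr in years:
        rec = {"year": yr}
        for gas in ("CO2", "CH4"):
            g = member_mass[gas][yr]
            totals = np.nansum(np.where(np.isfinite(g), g, 0.0), axis=(1, 2)) / accounting.G_PER_MMT
            rec[f"{gas.lower()}_mass_mmt"] = float(totals.mean())
            rec[f"{gas.lower()}_sd_mmt"] = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
        co2eq_members = (
            np.nansum(np.where(np.isfinite(member_mass["CO2"][yr]), member_mass["CO2"][yr], 0.0), axis=(1, 2))
            + acc.gwp_ch4
            * np.nansum(np.where(np.isfinite(member_mass["CH4"][yr]), member_mass["CH4"][yr], 0.0), axis=(1, 2))
        ) / accounting.G_PER_MMT
        rec["co2eq_mmt"] = float(co2eq_members.mean())
        rec["co2eq_sd_mmt"] = float(co2eq_members.std(ddof=1)) if len(co2eq_members) > 1 else 0.0
        rec["offset_pct"] = accounting.offset_ratio(
            rec["ch4_mass_mmt"], rec["co2_mass_mmt"], acc)
        regional.append(rec)
    regional = pd.DataFrame(regional)

    # per-habitat multi-year offsets
    hab_rows = []
    labels = sim["hab_map"].labels
    for hab in synth.HABITATS:
        sel = sim["hab_map"].mask(hab)
        if not sel.any():
            continue
        co2_m = np.nanmean([np.nansum(np.where(sel, annual_mean_mass["CO2"][yr], np.nan))
                            for yr in years])
        ch4_m = np.nanmean([np.nansum(np.where(sel, annual_mean_mass["CH4"][yr], np.nan))
                            for yr in years])
        hab_rows.append({
            "habitat": hab, "n_pixels": int(sel.sum()),
            "co2_mass_mmt": co2_m / accounting.G_PER_MMT,
            "ch4_mass_mmt": ch4_m / accounting.G_PER_MMT,
            "co2eq_mmt": accounting.co2eq(co2_m, ch4_m, acc) / accounting.G_PER_MMT,
            "offset_pct": accounting.offset_ratio(ch4_m, co2_m, acc),
        })
    habitat_budget = pd.DataFrame(hab_rows)

    # per-unit annual CO2eq series with ensemble SD
    unit_rows = []
    for yr in years:
        eq_members = accounting.co2eq(member_mass["CO2"][yr], member_mass["CH4"][yr], acc)
        per_unit = accounting.aggregate_by_unit(eq_members, sim["unit_map"])
        for unit, rec in per_unit.items():
            unit_rows.append({"unit_id": unit, "year": yr,
                              "co2eq_mmt": rec["total"] / accounting.G_PER_MMT,
                              "co2eq_sd_mmt": rec["sd"] / accounting.G_PER_MMT})
    unit_series = pd.DataFrame(unit_rows)
    return {"member_mass": member_mass, "annual_mean_mass": annual_mean_mass,
            "years": years, "regional": regional,
            "habitat_budget": habitat_budget, "unit_series": unit_series}


def trend_stage(config: PipelineConfig, sim: dict, acct: dict) -> dict | None:
    years = acct["years"]
    if len(years) < 4:
        logger.info("trend stage skipped: %d annual layers < 4", len(years))
        return None
    acc = config.accounting
    stack = np.stack([
        accounting.co2eq(acct["annual_mean_mass"]["CO2"][yr],
                         acct["annual_mean_mass"]["CH4"][yr], acc)
        for yr in years]) / accounting.G_PER_MMT
    per_pixel = accounting.trend_map(stack)
    unit_trends = {}
    for unit, sub in acct["unit_series"].groupby("unit_id"):
        sub = sub.sort_values("year")
        if len(sub) >= 4:
            res = accounting.mann_kendall(sub["co2eq_mmt"].to_numpy())
            unit_trends[int(unit)] = {"sen_slope": res.sen_slope, "tau": res.tau,
                                      "p": res.p_value}
    return {"per_pixel": per_pixel, "per_unit": unit_trends, "years": years}


def attribution_stage(config: PipelineConfig, sim: dict, acct: dict,
                      trends: dict | None) -> dict:
    footprints = synth.disturbance_footprints(config.scenario)
    mangrove = sim["hab_map"].mask("mangrove")
    ghost = mangrove & footprints.get("hurricane", np.zeros_like(mangrove))
    burned = footprints.get("fire", np.zeros_like(mangrove))
    indicators = {"pct_ghost_forest": 100.0 * ghost.astype(float),
                  "pct_burned": 100.0 * burned.astype(float)}
    trend_per_unit = None
    if trends:
        trend_per_unit = {"co2eq_trend": {u: rec["sen_slope"]
                                          for u, rec in trends["per_unit"].items()}}
    mean_mass = {gas: {yr: acct["annual_mean_mass"][gas][yr] / accounting.G_PER_MMT
                       for yr in acct["years"]}
                 for gas in ("CO2", "CH4")}
    summaries = attribution.build_unit_summaries(
        sim["unit_map"], sim["hab_map"], mean_mass,
        indicator_rasters=indicators, trend_per_unit=trend_per_unit)

    variables = [v for v in PCA_VARIABLES if v in summaries.columns
                 and summaries[v].std(ddof=1) > 0]
    kept, pca_result = attribution.prune_variables(
        summaries, variables, threshold=config.pca_threshold,
        protect=("mean_co2", "mean_ch4"))
    usable_edges = [e for e in config.path_spec
                    if e[0] in summaries.columns and e[1] in summaries.columns
                    and summaries[e[0]].std(ddof=1) > 0 and summaries[e[1]].std(ddof=1) > 0]
    path = attribution.fit_path_model(usable_edges, summaries) if usable_edges else None
    return {"summaries": summaries, "pca": pca_result, "pca_variables": kept,
            "path": path,
            "hurricane_damage": attribution.hurricane_damage_ratio(ghost, mangrove)}


def run_all(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full pipeline; returns all stage artifacts plus a manifest."""
    stages = {}
    try:
        sim = stages["simulate"] = simulate_stage(config)
        ing = stages["ingest"] = ingest_stage(config, sim)
        cov = stages["covariates"] = covariate_stage(config, sim, ing)
        trained = stages["train"] = train_stage(config, cov)
        acct = stages["account"] = account_stage(config, sim, cov, trained)
        trends = stages["trend"] = trend_stage(config, sim, acct)
        attr = stages["attribution"] = attribution_stage(config, sim, acct, trends)
    except Exception as exc:
        done = list(stages)
        raise RuntimeError(f"pipeline failed after stages {done}: {exc}") from exc

    eval_tables = []
    for gas in ("CO2", "CH4"):
        tab = trained[gas]["evaluation"].copy()
        tab.insert(0, "gas", gas)
        eval_tables.append(tab)
    evaluation = pd.concat(eval_tables, ignore_index=True)

    manifest = {
        "config": config_to_dict(config),
        "seed": config.seed,
        "stages": {
            "simulate": _checksum(sim["hab_map"].labels, sim["cube"].values,
                                  sim["tower_hh"], sim["flight_samples"]),
            "ingest": _checksum(ing["training"]),
            "covariates": _checksum(cov["rows"]),
            "train": _checksum(evaluation),
            "account": _checksum(acct["regional"], acct["habitat_budget"]),
            "trend": _checksum(trends["per_pixel"]["sen_slope"]) if trends else None,
            "attribution": _checksum(attr["summaries"]),
        },
    }
    result = {"config": config, "manifest": manifest, "evaluation": evaluation,
              **stages}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ing["training"].to_csv(out_dir / "training_table.csv", index=False)
        evaluation.to_csv(out_dir / "evaluation.csv", index=False)
        acct["regional"].to_csv(out_dir / "regional_budget.csv", index=False)
        acct["habitat_budget"].to_csv(out_dir / "habitat_budget.csv", index=False)
        acct["unit_series"].to_csv(out_dir / "unit_co2eq_series.csv", index=False)
        attr["summaries"].to_csv(out_dir / "unit_summaries.csv", index=False)
        if attr["path"] is not None:
            attr["path"].edges.to_csv(out_dir / "path_coefficients.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
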