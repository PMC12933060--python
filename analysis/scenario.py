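"""Shared scenario definition and artifact store for the analysis scripts.

The analysis runs a 40x40-pixel, 4-year (2020-2023) variant of the default
scenario so that Mann-Kendall/Sen trend mapping (which needs at least four
annual layers) is exercised end to end.  Stage artifacts are passed between
the numbered scripts as pickles under scratch/; tables land in results/.
"""

import datetime as dt
import pickle
from pathlib import Path

from wetlandflux.pipeline import ModelConfig, PipelineConfig
from wetlandflux.synth import DisturbanceEvent, LandscapeConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def make_config(seed: int = 0) -> PipelineConfig:
    scenario = LandscapeConfig(
        n_rows=40, n_cols=40,
        start_date=dt.date(2020, 1, 1), end_date=dt.date(2023, 12, 31),
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


def save_stage(name: str, obj) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    with open(SCRATCH / f"{name}.pkl", "wb") as fh:
        pickle.dump(obj, fh)


def load_stage(name: str):
    path = SCRATCH / f"{name}.pkl"
    if not path.exists():
        raise SystemExit(f"missing {path}; run the earlier analysis scripts first")
    with open(path, "rb") as fh:
        return pickle.load(fh)


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
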