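#!/usr/bin/env python
"""Greenhouse-gas accounting and long-term trends.

Predicts annual-mean flux grids per ensemble member, converts them to mass
budgets (MMT CO2, Tg CH4), combines them into CO2 equivalents at GWP-100 =
27.0, computes regional and per-habitat CH4/CO2 offset ratios, aggregates
CO2eq per management unit with ensemble SD, and maps Mann-Kendall/Sen
trends per pixel and per unit over the four annual layers.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from scenario import load_stage, results_dir, save_stage

from wetlandflux import pipeline


def main():
    cfg = load_stage("config")
    sim = load_stage("sim")
    cov = load_stage("covariates")
    trained = load_stage("trained")
    acct = pipeline.account_stage(cfg, sim, cov, trained)
    trends = pipeline.trend_stage(cfg, sim, acct)
    save_stage("account", acct)
    save_stage("trend", trends)

    acct["regional"].to_csv(results_dir() / "regional_budget.csv", index=False)
    acct["habitat_budget"].to_csv(results_dir() / "habitat_budget.csv", index=False)
    acct["unit_series"].to_csv(results_dir() / "unit_co2eq_series.csv", index=False)
    print("regional annual budget (MMT; negative = uptake):")
    print(acct["regional"].to_string(index=False, float_format="%.4f"))
    print("per-habitat multi-year budget and CH4 offset of CO2 uptake:")
    print(acct["habitat_budget"].to_string(index=False, float_format="%.4f"))

    if trends is not None:
        unit_rows = [{"unit_id": u, **rec} for u, rec in trends["per_unit"].items()]
        pd.DataFrame(unit_rows).to_csv(results_dir() / "unit_trends.csv", index=False)
        sen = trends["per_pixel"]["sen_slope"]
        p = trends["per_pixel"]["p"]
        sig = np.isfinite(p) & (p < 0.05)
        print(f"per-pixel CO2eq trends over {len(trends['years'])} years: "
              f"median Sen slope {np.nanmedian(sen):.2e} MMT y-2, "
              f"{100 * sig.mean():.1f}% of pixels significant at p<0.05")


if __name__ == "__main__":
    main()
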