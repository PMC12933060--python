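import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wetlandflux.synth import (
    BANDS,
    LandscapeConfig,
    ReflectanceCube,
    generate_habitat_map,
    simulate_reflectance,
    simulate_true_fluxes,
)


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(
        n_rows=16, n_cols=16,
        start_date=dt.date(2021, 1, 1), end_date=dt.date(2021, 12, 31),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    hab = generate_habitat_map(small_config)
    cube = simulate_reflectance(hab, small_config)
    truth = simulate_true_fluxes(cube, hab, small_config)
    return {"config": small_config, "hab": hab, "cube": cube, "truth": truth}


@pytest.fixture(scope="session")
def noiseless_config():
    return LandscapeConfig(
        n_rows=12, n_cols=12,
        start_date=dt.date(2021, 1, 1), end_date=dt.date(2021, 6, 30),
        seed=3, reflectance_noise_sd=0.0, co2_noise_sd=0.0, ch4_noise_sd=0.0,
        qa_dropout_frac=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    hab = generate_habitat_map(noiseless_config)
    cube = simulate_reflectance(hab, noiseless_config)
    truth = simulate_true_fluxes(cube, hab, noiseless_config)
    return {"config": noiseless_config, "hab": hab, "cube": cube, "truth": truth}


def make_cube(values, dates=None, qa_good=None, water=None):
    """Hand-built reflectance cube for targeted masking tests."""
    values = np.asarray(values, dtype=float)
    n_t, n_b, n_r, n_c = values.shape
    assert n_b == len(BANDS)
    if dates is None:
        dates = pd.date_range("2021-01-01", periods=n_t, freq="D")
    if qa_good is None:
        qa_good = np.ones((n_t, n_r, n_c), dtype=bool)
    if water is None:
        water = np.zeros((n_t, n_r, n_c), dtype=bool)
    return ReflectanceCube(values=values, dates=pd.DatetimeIndex(dates),
                           bands=list(BANDS), qa_good=qa_good, water=water)
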