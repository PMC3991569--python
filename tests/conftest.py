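import numpy as np
import pandas as pd
import pytest

import soiltherm as st

#: Generating truth for the synthetic-site recovery experiments.
TRUE_PARAMS = st.SoilLayerParams(
    C_S=2.0e6,
    K_T=0.8,
    C_ICE=9.0e6,
    f_S=4.0,
    T_LOW=0.5,
    K_T_LOW=0.3,
    C_S_LOW=2.0e6,
    Z_S=0.29,
)

SPINUP = st.SimulationConfig(spinup_days=365)


def make_forcing(t_air, d_s=None, precip=None, start="2000-01-01"):
    """Small forcing series on a contiguous daily index."""
    t_air = np.asarray(t_air, dtype=float)
    dates = pd.date_range(start, periods=t_air.size, freq="D")
    if d_s is None:
        d_s = np.zeros_like(t_air)
    return st.ForcingSeries(dates, t_air, d_s=np.asarray(d_s, float), precip=precip)


@pytest.fixture(scope="session")
def boreal_weather():
    """Four years of middle-boreal synthetic weather with degree-day snow."""
    weather = st.generate_synthetic_weather(st.WeatherGenParams(seed=1), n_years=4)
    return st.simulate_snowpack(weather)


@pytest.fixture(scope="session")
def soil_fixture(boreal_weather):
    """Noisy gappy soil-temperature observations over 3 years + hidden truth."""
    observed, truth = st.generate_soil_fixture(
        boreal_weather, TRUE_PARAMS, obs_noise_sd=0.3, missing_frac=0.1,
        seed=2, config=SPINUP,
    )
    return observed, truth


@pytest.fixture(scope="session")
def recovery_result(boreal_weather, soil_fixture):
    """20k-run Monte Carlo calibration against the synthetic observations."""
    observed, _ = soil_fixture
    return st.run_monte_carlo(
        observed, boreal_weather, Z_S=TRUE_PARAMS.Z_S,
        n_runs=20_000, seed=3, config=SPINUP,
    )
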