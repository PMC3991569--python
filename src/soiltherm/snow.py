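"""Degree-day snowpack model and synthetic weather generation.

Scenario climate series carry air temperature and precipitation but no snow
depth, and snow observations at monitoring sites are patchy, so a minimal
single-layer degree-day model converts precipitation falling on cold days
into snow water equivalent (SWE) and melts it on warm days.  Snow depth is
SWE divided by a bulk density ratio.  This deliberately ignores energy
balance, compaction and canopy interception; simulated soil temperatures
under scenario climates are conditional on it.

The weather generator produces site-like daily series — a seasonal
sinusoid with AR(1) temperature noise, and Bernoulli-Gamma precipitation —
parameterised by default to a middle-boreal Swedish climatology
(annual mean 2.4 degC, roughly 580 mm yr^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    ForcingSeries,
    SimulationConfig,
    SoilLayerParams,
    simulate_series,
)

__all__ = [
    "SnowModelParams",
    "WeatherGenParams",
    "simulate_snowpack",
    "generate_synthetic_weather",
    "generate_soil_fixture",
]


@dataclass(frozen=True)
class SnowModelParams:
    """Degree-day snow model settings.

    T_thresh : rain/snow partition temperature, degC.
    melt_factor : melt per degree-day above threshold, mm SWE degC^-1 day^-1.
    density_ratio : bulk snow density relative to water; depth = SWE / ratio.
    """

    T_thresh: float = 0.0
    melt_factor: float = 3.0
    density_ratio: float = 0.25

    def __post_init__(self) -> None:
        if self.melt_factor < 0:
            raise ValueError(f"melt_factor must be >= 0, got {self.melt_factor}")
        if not (0.0 < self.density_ratio <= 1.0):
            raise ValueError(
                f"density_ratio must be in (0, 1], got {self.density_ratio}"
            )


def simulate_snowpack(
    forcing: ForcingSeries, params: Optional[SnowModelParams] = None
) -> ForcingSeries:
    """Fill snow depth from temperature and precipitation by degree-day bookkeeping.

    Daily update: precipitation on days colder than ``T_thresh`` accumulates
    as SWE; melt is ``melt_factor * (T_AIR - T_thresh)`` on warm days, capped
    at the available stock so SWE never goes negative.  Returns a new
    forcing series with ``d_s = SWE / density_ratio`` (mm).
    """
    if params is None:
        params = SnowModelParams()
    if forcing.precip is None:
        raise ValueError("snow model needs precipitation in the forcing series")
    if np.isnan(forcing.precip).any() or np.isnan(forcing.t_air).any():
        raise ValueError("snow model forcing must have no missing values")
    t_air = forcing.t_air
    precip = forcing.precip
    swe = np.empty(len(forcing))
    stock = 0.0
    for i in range(len(forcing)):
        snow_in = precip[i] if t_air[i] < params.T_thresh else 0.0
        potential_melt = params.melt_factor * max(0.0, t_air[i] - params.T_thresh)
        melt = min(stock + snow_in, potential_melt)
        stock = stock + snow_in - melt
        swe[i] = stock
    return forcing.with_snow(swe / params.density_ratio)


@dataclass(frozen=True)
class WeatherGenParams:
    """Synthetic daily weather settings.

    Temperature: ``annual_mean_T + seasonal_amplitude * sin(2*pi*(doy - peak_doy)/365.25)``
    plus AR(1) noise with coefficient ``ar1_coeff`` and innovation standard
    deviation ``noise_sd``.  ``peak_doy`` is the phase reference: with the
    default 105 the sinusoid peaks in mid-July.  Precipitation:
    Bernoulli(``wet_day_prob``) occurrence with Gamma-distributed wet-day
    amounts.  Defaults reproduce a middle-boreal climatology
    (2.4 degC, ~580 mm yr^-1).
    """

    annual_mean_T: float = 2.4
    seasonal_amplitude: float = 11.0
    ar1_coeff: float = 0.7
    noise_sd: float = 2.0
    wet_day_prob: float = 0.45
    precip_gamma_shape: float = 0.8
    precip_gamma_scale: float = 4.4
    peak_doy: float = 105.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0.0 <= self.ar1_coeff < 1.0):
            raise ValueError(f"ar1_coeff must be in [0, 1), got {self.ar1_coeff}")
        if not (0.0 <= self.wet_day_prob <= 1.0):
            raise ValueError(f"wet_day_prob must be in [0, 1], got {self.wet_day_prob}")
        if self.precip_gamma_shape <= 0 or self.precip_gamma_scale <= 0:
            raise ValueError("precipitation Gamma parameters must be positive")


def generate_synthetic_weather(
    params: Optional[WeatherGenParams] = None,
    n_years: int = 10,
    start: str = "1996-01-01",
) -> ForcingSeries:
    """Generate a reproducible daily temperature/precipitation series."""
    if params is None:
        params = WeatherGenParams()
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(start, periods=round(n_years * 365.25), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = params.annual_mean_T + params.seasonal_amplitude * np.sin(
        2.0 * np.pi * (doy - params.peak_doy) / 365.25
    )
    n = len(dates)
    noise = np.zeros(n)
    if params.noise_sd > 0:
        innov = rng.normal(0.0, params.noise_sd, size=n)
        e = 0.0
        for i in range(n):
            e = params.ar1_coeff * e + innov[i]
            noise[i] = e
    t_air = seasonal + noise
    wet = rng.random(n) < params.wet_day_prob
    amounts = rng.gamma(params.precip_gamma_shape, params.precip_gamma_scale, size=n)
    precip = np.where(wet, amounts, 0.0)
    return ForcingSeries(dates, t_air, precip=precip)


def generate_soil_fixture(
    weather: ForcingSeries,
    true_params: SoilLayerParams,
    obs_noise_sd: float = 0.3,
    missing_frac: float = 0.0,
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
) -> tuple[pd.Series, pd.Series]:
    """Manufacture a soil-temperature 'observation' series with known truth.

    Runs the recursion with ``true_params``, adds Gaussian observation
    noise, and masks a random fraction of days (mimicking the gaps typical
    of long-term monitoring records).  Returns ``(observed, truth)`` as
    daily series on the same dates, so calibration experiments can test
    parameter recovery against the hidden truth.
    """
    if weather.d_s is None:
        raise ValueError("weather needs snow depth (run simulate_snowpack first)")
    if not (0.0 <= missing_frac < 1.0):
        raise ValueError(f"missing_frac must be in [0, 1), got {missing_frac}")
    rng = np.random.default_rng(seed)
    truth = simulate_series(weather, true_params, config).to_series(name="truth")
    observed = truth.copy().rename("soil_temp")
    if obs_noise_sd > 0:
        observed = observed + rng.normal(0.0, obs_noise_sd, size=len(observed))
    if missing_frac > 0:
        mask = rng.random(len(observed)) < missing_frac
        observed[mask] = np.nan
    return observed, truth
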