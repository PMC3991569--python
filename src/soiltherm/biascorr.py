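"""Distribution mapping (quantile mapping) of climate-model series.

Regional climate model (RCM) output is biased relative to local station
climate.  Distribution mapping corrects a scenario value ``x`` by pushing
it through the model's control-period CDF and back through the observed
CDF fitted over the same window:

    x* = F_obs^-1( F_contr(x) )

Temperature uses a Gaussian, precipitation a Gamma fitted to wet days
only, one map per calendar month and variable.  Correcting the control
run itself therefore reproduces the observed distribution up to fitting
error — the defining round-trip property of the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .model import ForcingSeries

__all__ = [
    "DistributionMap",
    "fit_distribution_map",
    "apply_distribution_map",
    "bias_correct_series",
    "DistributionMapper",
]

#: CDF arguments are clipped to [EPS, 1-EPS]; beyond-range scenario values
#: map to the corresponding observed quantile rather than being extrapolated.
EPS = 1e-6

VARIABLES = ("temperature", "precipitation")
_FAMILY = {"temperature": "gaussian", "precipitation": "gamma"}
MIN_FIT_COUNT = 30


@dataclass(frozen=True)
class DistributionMap:
    """Fitted observed/control CDF pair for one variable in one calendar month.

    ``obs_params`` and ``contr_params`` are ``(mu, sigma)`` for the Gaussian
    (temperature) and ``(shape, scale)`` for the Gamma (precipitation).
    ``contr_wet_threshold`` differs from ``wet_threshold`` only when wet-day
    frequency adaptation is enabled at fit time.
    """

    variable: str
    month: int
    family: str
    obs_params: tuple[float, float]
    contr_params: tuple[float, float]
    wet_threshold: float = 0.1
    contr_wet_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1..12, got {self.month}")
        if self.family != _FAMILY[self.variable]:
            raise ValueError(
                f"{self.variable} must use the {_FAMILY[self.variable]} family"
            )
        for side, (p1, p2) in (("obs", self.obs_params), ("contr", self.contr_params)):
            if self.family == "gaussian" and p2 <= 0:
                raise ValueError(f"Gaussian sigma ({side}) must be positive, got {p2}")
            if self.family == "gamma" and (p1 <= 0 or p2 <= 0):
                raise ValueError(
                    f"Gamma parameters ({side}) must be positive, got {(p1, p2)}"
                )
        if self.contr_wet_threshold is None:
            object.__setattr__(self, "contr_wet_threshold", self.wet_threshold)


def _month_values(series: pd.Series, month: int) -> np.ndarray:
    idx = pd.DatetimeIndex(series.index)
    vals = series.to_numpy(dtype=float)[idx.month == month]
    return vals[np.isfinite(vals)]


def _fit_gaussian(values: np.ndarray) -> tuple[float, float]:
    mu = float(np.mean(values))
    sigma = float(np.std(values))  # maximum-likelihood (ddof=0)
    if sigma <= 0:
        raise ValueError("cannot fit a Gaussian to constant values (sigma = 0)")
    return mu, sigma


def _fit_gamma(values: np.ndarray) -> tuple[float, float]:
    shape, _, scale = stats.gamma.fit(values, floc=0.0)
    return float(shape), float(scale)


def fit_distribution_map(
    obs: pd.Series,
    contr: pd.Series,
    variable: str,
    month: int,
    wet_threshold: float = 0.1,
    frequency_adaptation: bool = False,
) -> DistributionMap:
    """Fit the observed and control CDFs of one variable for one month.

    For precipitation only wet days (values above ``wet_threshold``) enter
    the Gamma fit.  With ``frequency_adaptation`` the control-side wet
    threshold is raised to the control quantile matching the observed
    dry-day frequency, so the corrected series has the observed wet-day
    frequency; off by default.

    Raises
    ------
    ValueError
        If fewer than 30 usable values remain on either side, naming the
        month and the offending count.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    obs_vals = _month_values(obs, month)
    contr_vals = _month_values(contr, month)

    contr_thr = wet_threshold
    if variable == "precipitation":
        if frequency_adaptation and len(contr_vals):
            obs_dry_frac = float(np.mean(obs_vals <= wet_threshold))
            contr_thr = max(
                wet_threshold, float(np.quantile(contr_vals, obs_dry_frac))
            )
        obs_vals = obs_vals[obs_vals > wet_threshold]
        contr_vals = contr_vals[contr_vals > contr_thr]

    for side, vals in (("observed", obs_vals), ("control", contr_vals)):
        if len(vals) < MIN_FIT_COUNT:
            what = "wet days" if variable == "precipitation" else "values"
            raise ValueError(
                f"month {month}: only {len(vals)} usable {side} {what} "
                f"(need >= {MIN_FIT_COUNT})"
            )

    fit = _fit_gaussian if variable == "temperature" else _fit_gamma
    return DistributionMap(
        variable=variable,
        month=month,
        family=_FAMILY[variable],
        obs_params=fit(obs_vals),
        contr_params=fit(contr_vals),
        wet_threshold=wet_threshold,
        contr_wet_threshold=contr_thr,
    )


def apply_distribution_map(
    x: Union[float, np.ndarray], dmap: DistributionMap
) -> Union[float, np.ndarray]:
    """Quantile-map value(s) through F_obs^-1 o F_contr.

    Monotone non-decreasing in ``x``.  Precipitation at or below the
    control wet threshold maps to 0 (a dry day stays dry); CDF arguments
    are clipped to [EPS, 1-EPS] so out-of-range extremes map to extreme
    observed quantiles instead of infinities.
    """
    arr = np.asarray(x, dtype=float)
    if dmap.family == "gaussian":
        mu_c, sd_c = dmap.contr_params
        mu_o, sd_o = dmap.obs_params
        u = np.clip(stats.norm.cdf(arr, mu_c, sd_c), EPS, 1.0 - EPS)
        out = stats.norm.ppf(u, mu_o, sd_o)
    else:
        a_c, s_c = dmap.contr_params
        a_o, s_o = dmap.obs_params
        u = np.clip(stats.gamma.cdf(arr, a_c, scale=s_c), EPS, 1.0 - EPS)
        out = np.where(
            arr <= dmap.contr_wet_threshold,
            0.0,
            stats.gamma.ppf(u, a_o, scale=s_o),
        )
    return float(out) if np.isscalar(x) else out


MapSet = Mapping[tuple[str, int], DistributionMap]


def _check_coverage(maps: MapSet, variables: Iterable[str]) -> None:
    for var in variables:
        for month in range(1, 13):
            if (var, month) not in maps:
                raise ValueError(f"no distribution map for {var}, month {month}")


def bias_correct_series(scen: ForcingSeries, maps: MapSet) -> ForcingSeries:
    """Correct each day of a scenario forcing with its calendar-month map.

    Temperature is always corrected; precipitation is corrected when the
    forcing carries it.  Dates and snow depth pass through unchanged.
    """
    variables = ["temperature"] + (
        ["precipitation"] if scen.precip is not None else []
    )
    _check_coverage(maps, variables)
    months = scen.dates.month.to_numpy()
    t_air = scen.t_air.copy()
    precip = None if scen.precip is None else scen.precip.copy()
    for month in range(1, 13):
        sel = months == month
        if not sel.any():
            continue
        t_air[sel] = apply_distribution_map(t_air[sel], maps[("temperature", month)])
        if precip is not None:
            precip[sel] = apply_distribution_map(
                precip[sel], maps[("precipitation", month)]
            )
    return ForcingSeries(scen.dates, t_air, d_s=scen.d_s, precip=precip)


class DistributionMapper:
    """Fit-then-transform interface over the per-month distribution maps.

    ``fit`` learns one map per calendar month for temperature (and
    precipitation, when present) from observed and control forcing over
    the same control period; ``transform`` corrects a scenario forcing.
    """

    def __init__(
        self, wet_threshold: float = 0.1, frequency_adaptation: bool = False
    ) -> None:
        self.wet_threshold = wet_threshold
        self.frequency_adaptation = frequency_adaptation

    def fit(self, obs: ForcingSeries, contr: ForcingSeries) -> "DistributionMapper":
        maps: dict[tuple[str, int], DistributionMap] = {}
        obs_t = pd.Series(obs.t_air, index=obs.dates)
        contr_t = pd.Series(contr.t_air, index=contr.dates)
        do_precip = obs.precip is not None and contr.precip is not None
        for month in range(1, 13):
            maps[("temperature", month)] = fit_distribution_map(
                obs_t, contr_t, "temperature", month
            )
            if do_precip:
                maps[("precipitation", month)] = fit_distribution_map(
                    pd.Series(obs.precip, index=obs.dates),
                    pd.Series(contr.precip, index=contr.dates),
                    "precipitation",
                    month,
                    wet_threshold=self.wet_threshold,
                    frequency_adaptation=self.frequency_adaptation,
                )
        self.maps_ = maps
        return self

    def transform(self, scen: ForcingSeries) -> ForcingSeries:
        if not hasattr(self, "maps_"):
            raise ValueError("DistributionMapper is not fitted; call fit() first")
        return bias_correct_series(scen, self.maps_)

    # --- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (var, month), m in sorted(self.maps_.items()):
            rows.append(
                {
                    "variable": var,
                    "month": month,
                    "family": m.family,
                    "p1_obs": m.obs_params[0],
                    "p2_obs": m.obs_params[1],
                    "p1_contr": m.contr_params[0],
                    "p2_contr": m.contr_params[1],
                    "wet_threshold": m.wet_threshold,
                    "contr_wet_threshold": m.contr_wet_threshold,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistributionMapper":
        mapper = cls()
        maps = {}
        for _, row in frame.iterrows():
            m = DistributionMap(
                variable=row["variable"],
                month=int(row["month"]),
                family=row["family"],
                obs_params=(float(row["p1_obs"]), float(row["p2_obs"])),
                contr_params=(float(row["p1_contr"]), float(row["p2_contr"])),
                wet_threshold=float(row["wet_threshold"]),
                contr_wet_threshold=float(row.get("contr_wet_threshold", row["wet_threshold"])),
            )
            maps[(m.variable, m.month)] = m
        mapper.maps_ = maps
        return mapper
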