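"""Climate-ensemble projection of soil temperature.

Each ensemble member (a bias-corrected regional climate model series) is
simulated under every behavioral parameter set; the per-day median across
parameter sets is that member's projection.  The same reduction applied to
the control forcing gives the baseline, and scenario-minus-control monthly
climatologies give the change signal.  The ensemble median across members
summarises the multi-model spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import ForcingSeries, SimulationConfig, simulate_batch

__all__ = [
    "EnsembleProjection",
    "run_ensemble",
    "monthly_climatology",
    "annual_summary",
    "seasonal_delta",
    "seasonal_rollup",
]

SEASONS = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}


def monthly_climatology(series: pd.Series) -> pd.Series:
    """Calendar-month means over all years; index 1..12.

    Requires at least one full year of data (all 12 months present and
    >= 365 days) so the climatology is not a partial-season artifact.
    """
    idx = pd.DatetimeIndex(series.index)
    if len(series) < 365 or idx.month.nunique() < 12:
        raise ValueError(
            "monthly climatology needs at least one full year of daily data"
        )
    out = series.groupby(idx.month).mean()
    out.index.name = "month"
    return out.reindex(range(1, 13))


def annual_summary(series: pd.Series) -> pd.DataFrame:
    """Per-year mean and standard deviation over complete calendar years."""
    idx = pd.DatetimeIndex(series.index)
    frame = pd.DataFrame({"value": series.to_numpy(), "year": idx.year})
    counts = frame.groupby("year").size()
    expected = pd.Series(
        {y: 366 if pd.Timestamp(year=y, month=12, day=31).is_leap_year else 365
         for y in counts.index}
    )
    complete = counts[counts >= expected].index
    if len(complete) == 0:
        raise ValueError("annual summary needs at least one complete calendar year")
    g = frame[frame["year"].isin(complete)].groupby("year")["value"]
    return pd.DataFrame({"annual_mean": g.mean(), "annual_sd": g.std(ddof=1)})


def seasonal_delta(scenario: pd.Series, control: pd.Series) -> pd.Series:
    """Scenario minus control monthly climatology, 12 values."""
    return monthly_climatology(scenario) - monthly_climatology(control)


def seasonal_rollup(monthly: pd.Series) -> pd.Series:
    """Collapse a month-indexed series to DJF/MAM/JJA/SON means."""
    return pd.Series(
        {name: monthly.loc[list(months)].mean() for name, months in SEASONS.items()}
    )


@dataclass
class EnsembleProjection:
    """Projection results for a set of ensemble members.

    ``monthly`` is tidy: one row per (member, month) with control mean,
    scenario mean and delta.  ``annual`` has one row per (member, year).
    ``ensemble_median_delta`` is the across-member median of the monthly
    deltas, and ``member_daily`` / ``control_daily`` keep the reduced
    (across behavioral runs) daily series.
    """

    members: list[str]
    member_daily: dict[str, pd.Series]
    control_daily: pd.Series
    monthly: pd.DataFrame
    annual: pd.DataFrame
    control_annual: pd.DataFrame
    ensemble_median_delta: pd.Series


def _median_projection(
    forcing: ForcingSeries,
    behavioral: pd.DataFrame,
    Z_S: float,
    Z_l: Optional[float],
    config: SimulationConfig,
) -> pd.Series:
    sims = simulate_batch(
        forcing, behavioral.to_numpy(dtype=float), Z_S, Z_l, config
    )
    dates = forcing.dates[config.spinup_days:]
    return pd.Series(np.median(sims, axis=1), index=dates.rename("date"))


def run_ensemble(
    behavioral: pd.DataFrame,
    scenario_forcings: Mapping[str, ForcingSeries],
    control_forcing: ForcingSeries,
    Z_S: float,
    Z_l: Optional[float] = None,
    config: Optional[SimulationConfig] = None,
) -> EnsembleProjection:
    """Simulate behavioral parameter sets under every ensemble member.

    Parameters
    ----------
    behavioral : DataFrame, shape (n_sets, 7)
        Behavioral parameter matrix (columns in CALIBRATABLE order).
    scenario_forcings : mapping of member label -> ForcingSeries
        Bias-corrected scenario climate per ensemble member (snow depth
        filled, e.g. by the degree-day snow model).
    control_forcing : ForcingSeries
        Present-day forcing reduced by the identical procedure.
    """
    if len(behavioral) == 0:
        raise ValueError("behavioral parameter set is empty")
    if len(scenario_forcings) == 0:
        raise ValueError("need at least one ensemble member")
    if config is None:
        config = SimulationConfig()

    control_daily = _median_projection(
        control_forcing, behavioral, Z_S, Z_l, config
    )
    control_clim = monthly_climatology(control_daily)
    control_annual = annual_summary(control_daily)

    member_daily: dict[str, pd.Series] = {}
    monthly_rows = []
    annual_frames = []
    deltas = {}
    for label, forcing in scenario_forcings.items():
        try:
            daily = _median_projection(forcing, behavioral, Z_S, Z_l, config)
        except ValueError as exc:
            raise ValueError(f"ensemble member {label!r}: {exc}") from exc
        member_daily[label] = daily
        clim = monthly_climatology(daily)
        delta = clim - control_clim
        deltas[label] = delta
        for month in range(1, 13):
            monthly_rows.append(
                {
                    "member": label,
                    "month": month,
                    "control_mean": control_clim.loc[month],
                    "scenario_mean": clim.loc[month],
                    "delta": delta.loc[month],
                }
            )
        ann = annual_summary(daily).reset_index()
        ann.insert(0, "member", label)
        annual_frames.append(ann)

    delta_table = pd.DataFrame(deltas)
    return EnsembleProjection(
        members=list(scenario_forcings),
        member_daily=member_daily,
        control_daily=control_daily,
        monthly=pd.DataFrame(monthly_rows),
        annual=pd.concat(annual_frames, ignore_index=True),
        control_annual=control_annual.reset_index(),
        ensemble_median_delta=delta_table.median(axis=1),
    )
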