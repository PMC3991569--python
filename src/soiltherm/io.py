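"""CSV / JSON persistence for daily series and parameter sets.

Daily series are stored as two-column CSV (``date,<value>``) with ISO-8601
dates and empty fields for missing values.  Reading re-indexes onto the
full daily span, so gap days appear as missing markers: acceptable for
observations, rejected later by the simulator for forcing.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model import ForcingSeries, SoilLayerParams

__all__ = [
    "read_daily_series",
    "write_daily_series",
    "read_forcing",
    "write_forcing",
    "load_params",
    "save_params",
    "atomic_write_text",
]

PathLike = Union[str, Path]


def atomic_write_text(path: PathLike, text: str) -> None:
    """Write a text file atomically (temp file + rename in the same dir)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_dated_frame(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "date" not in frame.columns:
        raise ValueError(f"{path}: missing 'date' column")
    try:
        dates = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date: {exc}") from exc
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate date {dup.date()}")
    frame = frame.drop(columns="date")
    frame.index = pd.DatetimeIndex(dates, name="date")
    frame = frame.sort_index()
    # expose gap days as missing markers on a contiguous daily index
    full = pd.date_range(frame.index[0], frame.index[-1], freq="D", name="date")
    return frame.reindex(full)


def read_daily_series(path: PathLike) -> pd.Series:
    """Read a ``date,value`` CSV into a daily series; gaps become NaN."""
    frame = _read_dated_frame(path)
    if frame.shape[1] != 1:
        raise ValueError(
            f"{path}: expected exactly one value column, got {list(frame.columns)}"
        )
    return frame.iloc[:, 0].astype(float)


def write_daily_series(series: pd.Series, path: PathLike, name: str = None) -> None:
    """Write a daily series as ``date,<name>`` CSV; NaN becomes an empty field.

    Days that are missing are still written (with empty value) so the file
    round-trips exactly through :func:`read_daily_series`.
    """
    s = series.copy()
    if name is not None:
        s = s.rename(name)
    elif s.name is None:
        s = s.rename("value")
    frame = s.to_frame()
    frame.index = pd.DatetimeIndex(frame.index).strftime("%Y-%m-%d")
    frame.index.name = "date"
    atomic_write_text(path, frame.to_csv())


def read_forcing(path: PathLike) -> ForcingSeries:
    """Read a daily forcing CSV (``date,t_air[,d_s][,precip]``)."""
    frame = _read_dated_frame(path)
    if "t_air" not in frame.columns:
        raise ValueError(f"{path}: forcing file must have a 't_air' column")
    return ForcingSeries.from_frame(frame)


def write_forcing(forcing: ForcingSeries, path: PathLike) -> None:
    frame = forcing.to_frame()
    frame.index = frame.index.strftime("%Y-%m-%d")
    frame.index.name = "date"
    atomic_write_text(path, frame.to_csv())


def save_params(params: SoilLayerParams, path: PathLike) -> None:
    """Write layer parameters as a flat JSON key-value document."""
    atomic_write_text(path, json.dumps(params.to_dict(), indent=2) + "\n")


def load_params(path: PathLike) -> SoilLayerParams:
    with open(path) as fh:
        return SoilLayerParams.from_dict(json.load(fh))
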