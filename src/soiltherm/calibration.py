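"""Monte Carlo calibration of the soil-temperature model.

The seven layer parameters are drawn independently and uniformly from
physically motivated ranges, the model is run once per draw, and runs are
ranked by Nash-Sutcliffe efficiency (NS) over the calibration window — the
first two thirds (by count) of the non-missing observations.  The
remaining third is the validation window, reported with NS, R² and RMSE.
Posterior cumulative distributions of the best 5000 runs diagnose
parameter sensitivity (a flat, uniform-like CDF marks an insensitive
parameter — equifinality); the top 100 runs form the behavioral set
carried into climate projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

from .model import CALIBRATABLE, ForcingSeries, SimulationConfig, simulate_batch

__all__ = [
    "ParameterRanges",
    "CalibrationResult",
    "split_calibration_validation",
    "nash_sutcliffe",
    "rmse",
    "r_squared",
    "run_monte_carlo",
    "posterior_cdf",
    "ks_uniform_distance",
    "select_behavioral",
]

MIN_OBSERVATIONS = 30


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform sampling bounds per calibratable parameter.

    Defaults are the standard Monte Carlo ranges for boreal till soils:
    heat capacities 0.5-3.5e6 J m^-3 degC^-1, conductivities 0-1
    W m^-1 degC^-1, latent capacity 4-15e6 J m^-3 degC^-1, snow parameter
    0-10 m^-1, lower boundary temperature 0-1 degC.
    """

    C_S: tuple[float, float] = (0.5e6, 3.5e6)
    K_T: tuple[float, float] = (0.0, 1.0)
    C_ICE: tuple[float, float] = (4.0e6, 15.0e6)
    f_S: tuple[float, float] = (0.0, 10.0)
    T_LOW: tuple[float, float] = (0.0, 1.0)
    K_T_LOW: tuple[float, float] = (0.0, 1.0)
    C_S_LOW: tuple[float, float] = (0.5e6, 3.5e6)

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = getattr(self, f.name)
            if not (lo < hi):
                raise ValueError(f"{f.name}: lower bound {lo} must be < upper {hi}")

    def bounds(self, name: str) -> tuple[float, float]:
        if name not in CALIBRATABLE:
            raise KeyError(f"unknown parameter {name!r}")
        return getattr(self, name)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n independent uniform parameter vectors, shape (n, 7)."""
        out = np.empty((n, len(CALIBRATABLE)))
        for j, name in enumerate(CALIBRATABLE):
            lo, hi = getattr(self, name)
            out[:, j] = rng.uniform(lo, hi, size=n)
        return out

    def normalize(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds(name)
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)


def _paired(obs, sim) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float).ravel()
    s = np.asarray(sim, dtype=float).ravel()
    if o.shape != s.shape:
        raise ValueError("obs and sim must have the same length")
    keep = np.isfinite(o) & np.isfinite(s)
    o, s = o[keep], s[keep]
    if o.size < 2:
        raise ValueError(f"need >= 2 paired non-missing values, got {o.size}")
    return o, s


def nash_sutcliffe(obs, sim) -> float:
    """Nash-Sutcliffe efficiency: 1 - SSE / SST; 1 is perfect, 0 matches the mean.

    Computed over paired non-missing days only.  Undefined (raises) when
    the observations are constant.
    """
    o, s = _paired(obs, sim)
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("Nash-Sutcliffe undefined for constant observations")
    return 1.0 - float(np.sum((o - s) ** 2)) / sst


def rmse(obs, sim) -> float:
    """Root mean square error over paired non-missing days."""
    o, s = _paired(obs, sim)
    return float(np.sqrt(np.mean((o - s) ** 2)))


def r_squared(obs, sim) -> float:
    """Squared Pearson correlation of paired non-missing values."""
    o, s = _paired(obs, sim)
    so, ss = o.std(), s.std()
    if so == 0 or ss == 0:
        raise ValueError("R^2 undefined when either side is constant")
    r = float(np.mean((o - o.mean()) * (s - s.mean())) / (so * ss))
    return r * r


def split_calibration_validation(obs: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Split non-missing observations into calibration and validation masks.

    The first ``ceil(2n/3)`` non-missing observations (in time order) form
    the calibration window; the rest validate.  Returns two boolean masks
    aligned to ``obs`` that are disjoint and together cover exactly the
    non-missing entries.
    """
    vals = np.asarray(obs, dtype=float)
    present = np.isfinite(vals)
    n = int(present.sum())
    if n < MIN_OBSERVATIONS:
        raise ValueError(
            f"need >= {MIN_OBSERVATIONS} non-missing observations, got {n}"
        )
    n_cal = math.ceil(2 * n / 3)
    order = np.nonzero(present)[0]  # already in time order
    cal = np.zeros_like(present)
    val = np.zeros_like(present)
    cal[order[:n_cal]] = True
    val[order[n_cal:]] = True
    return cal, val


@dataclass
class CalibrationResult:
    """Sampled parameter matrix with scores, ranks and behavioral flags.

    ``params`` has one row per run (columns in CALIBRATABLE order);
    ``scores`` carries calibration-window NS, validation NS/R²/RMSE, the
    1-based rank by calibration NS (ties broken by run index), and the
    top-5000 / top-100 membership flags.
    """

    params: pd.DataFrame
    scores: pd.DataFrame
    ranges: ParameterRanges
    seed: int
    n_runs: int
    Z_S: float
    Z_l: float
    n_cal: int
    n_val: int

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.params, self.scores], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="run")

    @property
    def best_index(self) -> int:
        return int(self.scores.index[self.scores["rank"] == 1][0])

    @property
    def best_ns(self) -> float:
        return float(self.scores.loc[self.best_index, "ns_cal"])


def _score_columns(obs: np.ndarray, sim: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised NS/R²/RMSE of many simulations against one observation vector.

    ``sim`` has shape (n_days, n_runs).  Degenerate runs (constant
    simulation) get R² = NaN instead of raising; they can never rank first
    on real data anyway.
    """
    o = obs[:, None]
    resid = o - sim
    sse = np.sum(resid**2, axis=0)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant observation window: NS undefined")
    ns = 1.0 - sse / sst
    rmse_ = np.sqrt(sse / obs.size)
    s_centered = sim - sim.mean(axis=0)
    o_centered = obs - obs.mean()
    denom = np.sqrt(np.sum(o_centered**2) * np.sum(s_centered**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (o_centered @ s_centered) / denom, np.nan)
    return {"ns": ns, "rmse": rmse_, "r2": r * r}


def run_monte_carlo(
    obs: pd.Series,
    forcing: ForcingSeries,
    Z_S: float,
    ranges: Optional[ParameterRanges] = None,
    n_runs: int = 100_000,
    seed: int = 0,
    Z_l: Optional[float] = None,
    config: Optional[SimulationConfig] = None,
    chunk_size: int = 10_000,
) -> CalibrationResult:
    """Sample, simulate and score ``n_runs`` random parameter sets.

    Every run sees the identical forcing; scoring uses the calibration /
    validation split of the non-missing observations.  Reproducible under
    ``seed``.  Simulation is chunked so memory stays bounded at
    ``chunk_size`` concurrent runs.
    """
    if ranges is None:
        ranges = ParameterRanges()
    if config is None:
        config = SimulationConfig()
    if Z_l is None:
        Z_l = 2.0 * Z_S
    obs = obs.sort_index()
    cal_mask, val_mask = split_calibration_validation(obs)

    sim_dates = forcing.dates[config.spinup_days:]
    pos = sim_dates.get_indexer(pd.DatetimeIndex(obs.index))
    if (pos < 0).any():
        missing = pd.DatetimeIndex(obs.index)[pos < 0][0]
        raise ValueError(
            f"forcing (after spin-up) does not cover observation date "
            f"{missing.date()}"
        )
    obs_vals = obs.to_numpy(dtype=float)
    o_cal = obs_vals[cal_mask]
    o_val = obs_vals[val_mask]
    pos_cal = pos[cal_mask]
    pos_val = pos[val_mask]

    rng = np.random.default_rng(seed)
    P = ranges.sample(n_runs, rng)

    ns_cal = np.empty(n_runs)
    ns_val = np.empty(n_runs)
    r2_val = np.empty(n_runs)
    rmse_val = np.empty(n_runs)
    for start in range(0, n_runs, chunk_size):
        stop = min(start + chunk_size, n_runs)
        sim = simulate_batch(forcing, P[start:stop], Z_S, Z_l, config)
        cal_scores = _score_columns(o_cal, sim[pos_cal])
        val_scores = _score_columns(o_val, sim[pos_val])
        ns_cal[start:stop] = cal_scores["ns"]
        ns_val[start:stop] = val_scores["ns"]
        r2_val[start:stop] = val_scores["r2"]
        rmse_val[start:stop] = val_scores["rmse"]

    # rank 1 = highest calibration NS; ties broken by run index (lower first)
    order = np.lexsort((np.arange(n_runs), -ns_cal))
    rank = np.empty(n_runs, dtype=int)
    rank[order] = np.arange(1, n_runs + 1)

    params = pd.DataFrame(P, columns=list(CALIBRATABLE))
    scores = pd.DataFrame(
        {
            "ns_cal": ns_cal,
            "ns_val": ns_val,
            "r2_val": r2_val,
            "rmse_val": rmse_val,
            "rank": rank,
            "top5000": rank <= min(5000, n_runs),
            "top100": rank <= min(100, n_runs),
        }
    )
    return CalibrationResult(
        params=params,
        scores=scores,
        ranges=ranges,
        seed=seed,
        n_runs=n_runs,
        Z_S=Z_S,
        Z_l=Z_l,
        n_cal=int(cal_mask.sum()),
        n_val=int(val_mask.sum()),
    )


def posterior_cdf(
    result: CalibrationResult, parameter: str, top_k: int = 5000
) -> pd.DataFrame:
    """Empirical CDF of one parameter over the best ``top_k`` runs.

    Values are normalised to [0, 1] by the sampling range so CDFs of
    different parameters are comparable; a sensitive parameter bends away
    from the diagonal, an insensitive one stays close to uniform.
    """
    if parameter not in CALIBRATABLE:
        raise KeyError(f"unknown parameter {parameter!r}")
    if result.n_runs < top_k:
        raise ValueError(
            f"top_k={top_k} exceeds the number of runs ({result.n_runs})"
        )
    sel = result.scores["rank"] <= top_k
    values = result.ranges.normalize(parameter, result.params.loc[sel, parameter])
    values = np.sort(values)
    cdf = np.arange(1, values.size + 1) / values.size
    return pd.DataFrame({"value": values, "cdf": cdf})


def ks_uniform_distance(cdf_table: pd.DataFrame) -> float:
    """Kolmogorov-Smirnov distance of an empirical CDF from Uniform(0, 1)."""
    x = cdf_table["value"].to_numpy()
    upper = cdf_table["cdf"].to_numpy()
    lower = upper - 1.0 / x.size
    return float(np.max(np.maximum(np.abs(upper - x), np.abs(lower - x))))


def select_behavioral(result: CalibrationResult, top_n: int = 100) -> pd.DataFrame:
    """Parameter rows of the best ``top_n`` runs by calibration NS.

    Rows are ordered by rank; the index keeps the original run indices.
    """
    if result.n_runs < top_n:
        raise ValueError(f"top_n={top_n} exceeds the number of runs ({result.n_runs})")
    sel = result.scores.sort_values("rank").index[:top_n]
    return result.params.loc[sel]
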