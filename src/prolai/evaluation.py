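"""Benchmark metrics and temporal aggregation for LAI series.

Provides the standard skill scores used to compare a simulated LAI series
against a reference (satellite or flux-derived) series — Pearson r, R²
(squared Pearson correlation), RMSE, relative RMSE in percent of the
observed mean, mean bias and the regression slope — at several temporal
aggregation levels: 7-day blocks, month-of-year climatology, annual means,
or multi-year ("spatial") means per site.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

AGG_LEVELS = ("daily", "7day", "monthly", "annual", "spatial")


@dataclass(frozen=True)
class EvalReport:
    n: int
    pearson_r: Optional[float]
    r2: Optional[float]
    rmse: float
    rrmse_percent: Optional[float]
    bias: float
    slope: Optional[float]
    level: str

    def to_dict(self) -> dict:
        return asdict(self)


def aggregate(series: pd.Series, level: str,
              site: Optional[pd.Series] = None) -> pd.Series:
    """Aggregate a date-indexed daily series.

    Levels: ``daily`` (identity), ``7day`` (mean over consecutive 7-day
    blocks anchored at 1 January of each year; a final short block is kept),
    ``monthly`` (mean by calendar month of year, pooling years), ``annual``
    (mean by year), ``spatial`` (multi-year mean per site; requires an
    aligned ``site`` series, or collapses to a single overall mean).
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if level not in AGG_LEVELS:
        raise ValueError(f"unknown aggregation level {level!r}; "
                         f"choose from {AGG_LEVELS}")
    idx = pd.DatetimeIndex(series.index)
    if level == "daily":
        return series
    if level == "7day":
        block = (idx.dayofyear - 1) // 7
        return series.groupby([idx.year, block]).mean()
    if level == "monthly":
        return series.groupby(idx.month).mean()
    if level == "annual":
        return series.groupby(idx.year).mean()
    # spatial
    if site is None:
        return pd.Series({"all": series.mean()})
    return series.groupby(np.asarray(site)).mean()


def evaluate(sim: pd.Series, obs: pd.Series, level: str = "daily",
             site: Optional[pd.Series] = None) -> EvalReport:
    """Compare simulated against observed values at an aggregation level.

    Both series must be daily and date-indexed (unless ``level='daily'``
    with plain aligned indexes); they are aggregated, inner-joined, and
    scored. With zero variance in either aggregated series the correlation
    and slope are undefined and reported as None; RMSE and bias are still
    computed.
    """
    s = aggregate(sim, level, site)
    o = aggregate(obs, level, site)
    joined = pd.concat({"sim": s, "obs": o}, axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 aligned values, got {n}")
    x = joined["obs"].to_numpy(dtype=float)
    y = joined["sim"].to_numpy(dtype=float)

    err = y - x
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    mean_obs = float(np.mean(x))
    rrmse = 100.0 * rmse / mean_obs if mean_obs != 0 else None

    if np.std(x) == 0 or np.std(y) == 0:
        r = r2 = slope = None
    else:
        reg = stats.linregress(x, y)
        r = float(reg.rvalue)
        r2 = r * r
        slope = float(reg.slope)

    return EvalReport(n=n, pearson_r=r, r2=r2, rmse=rmse,
                      rrmse_percent=rrmse, bias=bias, slope=slope,
                      level=level)
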