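"""Allocation ratio m, growing-season length, and σ calibration.

m is the steady-state LAI per unit steady-state GPP. It cannot be read off
daily data directly (actual LAI lags the steady state), but annually it is
well approximated by mean(LAI)/mean(GPP), and the square-wave argument of
Xia et al. links it to annual aggregates:

    m = σ · GSL · LAI_max / (A0sum · fAPAR_max)

with GSL the growing-season length in days, A0sum the annual total potential
GPP in g C m⁻² yr⁻¹ (so that μ = m·A₀ daily carries LAI units), and σ a
single dimensionless shape factor absorbing how far the real seasonal course
departs from a square wave at LAI_max.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .canopy import AnnualDrivers, CanopyLimits


def growing_season_length(tair_series: Sequence[float],
                          frost: float = 0.0,
                          min_run: int = 5) -> int:
    """Growing season length: longest run of consecutive days above frost.

    Returns the length of the longest continuous above-0 °C run if it
    exceeds ``min_run`` days, else 0.
    """
    t = np.asarray(tair_series, dtype=float)
    if t.size == 0:
        raise ValueError("empty temperature series")
    warm = t > frost
    best = run = 0
    for w in warm:
        run = run + 1 if w else 0
        if run > best:
            best = run
    return best if best > min_run else 0


def m_from_drivers(drivers: AnnualDrivers, limits: CanopyLimits,
                   sigma: float) -> float:
    """Allocation ratio m = σ·GSL·LAI_max/(A0sum·fAPAR_max); 0 if dormant.

    ``A0sum`` enters in g C m⁻² yr⁻¹, so m has units of m² m⁻² per
    (g C m⁻² d⁻¹).
    """
    if sigma < 0 or drivers.a0sum_gc < 0:
        raise ValueError("negative inputs")
    if limits.fapar_max <= 0 or drivers.a0sum_gc <= 0 or drivers.gsl == 0:
        return 0.0
    return sigma * drivers.gsl * limits.lai_max / (
        drivers.a0sum_gc * limits.fapar_max
    )


def observed_m(lai_daily: Sequence[float],
               gpp_daily: Sequence[float]) -> float:
    """Empirical m for one year: mean(LAI) / mean(GPP)."""
    lai = np.asarray(lai_daily, dtype=float)
    gpp = np.asarray(gpp_daily, dtype=float)
    if lai.shape != gpp.shape:
        raise ValueError("series must be aligned")
    mg = gpp.mean()
    if not mg > 0:
        raise ValueError("mean GPP must be > 0")
    return float(lai.mean() / mg)


SiteYear = Tuple[float, float, float, float, float]
# (observed_m, gsl_days, lai_max, a0sum_gc, fapar_max)


def fit_sigma(site_years: Sequence[SiteYear]) -> float:
    """Global σ from observed site-year allocation ratios.

    Least squares through the origin of observed m on the regressor
    x = GSL·LAI_max/(A0sum·fAPAR_max): σ̂ = Σxy/Σx². Exact when the data are
    noiseless; reduces to observed_m/x for a single site-year.
    """
    if len(site_years) == 0:
        raise ValueError("need at least one site-year")
    m_obs = np.array([s[0] for s in site_years], dtype=float)
    x = np.array(
        [s[1] * s[2] / (s[3] * s[4]) if s[3] > 0 and s[4] > 0 else 0.0
         for s in site_years],
        dtype=float,
    )
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all regressors are zero; sigma is unidentified")
    return float(np.dot(x, m_obs) / sxx)
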