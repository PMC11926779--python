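"""Full daily LAI simulation: drivers → limits → steady state → EMA lag.

For each calendar year the simulator aggregates the forcing into annual
drivers, predicts the canopy limits (fAPAR_max, LAI_max) and the allocation
ratio m; each day it computes potential GPP A₀, the steady-state LAI
L_s = min(μ + W₀-term, LAI_max) with μ = m·A₀, and the simulated actual LAI
as the exponential moving average

    LAI_sim(t) = α·L_s(t) + (1 − α)·LAI_sim(t − 1),

whose memory spans roughly 1/α days. EMA state persists across year
boundaries; by default the first year is run once as spin-up and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allocation import growing_season_length, m_from_drivers
from .canopy import AnnualDrivers, CanopyLimits, canopy_limits
from .constants import C_MOLMASS, MM_PRECIP_TO_MOL, DEFAULT_CONSTANTS, \
    ModelConstants
from .photosynthesis import photo_env, potential_gpp_series
from .steady_state import uncapped_steady_state_lai


@dataclass(frozen=True)
class LAITrajectory:
    """Result of a site simulation.

    ``daily`` has columns date, a0_gc_m2_d, ls, lai_sim; ``annual`` has one
    row per simulated year with the drivers, canopy limits and m.
    """

    daily: pd.DataFrame
    annual: pd.DataFrame


def alpha_from_memory_days(tau: float) -> float:
    """EMA smoothing factor for a memory of ``tau`` days: α = 1/τ.

    Reported to 3 decimals, e.g. 15 days → 0.067, 60 days → 0.017.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1 day")
    return round(1.0 / tau, 3)


def ema_update(prev_lai: float, ls_today: float, alpha: float) -> float:
    """One EMA step: α·L_s(today) + (1 − α)·LAI_sim(yesterday)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if prev_lai < 0 or ls_today < 0:
        raise ValueError("LAI values must be >= 0")
    return alpha * ls_today + (1.0 - alpha) * prev_lai


def annual_drivers(year_df: pd.DataFrame, ai: float,
                   constants: ModelConstants = DEFAULT_CONSTANTS,
                   a0: np.ndarray | None = None) -> AnnualDrivers:
    """Aggregate one calendar year of forcing into annual drivers.

    Growing-season statistics (mean VPD, χ, c_a) are taken over days with
    tair above the frost threshold; χ is evaluated once at the
    growing-season mean temperature, VPD, CO₂ and pressure. If the daily
    potential-GPP series ``a0`` was already computed it can be passed in.
    """
    year = int(pd.to_datetime(year_df["date"].iloc[0]).year)
    tair = year_df["tair_c"].to_numpy(dtype=float)
    if a0 is None:
        a0 = potential_gpp_series(
            tair,
            year_df["ppfd_mol_m2_d"].to_numpy(dtype=float),
            year_df["vpd_pa"].to_numpy(dtype=float),
            year_df["co2_ppm"].to_numpy(dtype=float),
            year_df["patm_pa"].to_numpy(dtype=float),
            constants=constants,
        )
    a0sum_gc = float(np.sum(a0))
    precip_mol = float(year_df["precip_mm"].sum()) * MM_PRECIP_TO_MOL
    gsl = growing_season_length(tair, frost=constants.tair_frost)

    gs_mask = tair > constants.tair_frost
    if gs_mask.any():
        t_gs = float(tair[gs_mask].mean())
        d_gs = float(np.maximum(year_df["vpd_pa"].to_numpy(dtype=float)
                                [gs_mask], constants.vpd_floor).mean())
        co2_gs = float(year_df["co2_ppm"].to_numpy(dtype=float)
                       [gs_mask].mean())
        patm_gs = float(year_df["patm_pa"].to_numpy(dtype=float)
                        [gs_mask].mean())
        env = photo_env(t_gs, d_gs, co2_gs, patm_gs, constants)
        chi_gs = float(env.chi)
        ca_gs = float(env.ca)
    else:
        d_gs = constants.vpd_floor
        chi_gs = 0.0
        ca_gs = 0.0

    return AnnualDrivers(
        year=year,
        a0sum_gc=a0sum_gc,
        a0sum_mol=a0sum_gc / C_MOLMASS,
        precip_mol=precip_mol,
        d_gs=d_gs,
        chi_gs=chi_gs,
        ca_gs=ca_gs,
        gsl=gsl,
        ai=ai,
    )


def _check_complete_years(dates: pd.Series) -> None:
    if len(dates) == 0:
        raise ValueError("empty forcing")
    dates = pd.to_datetime(dates)
    start = dates.iloc[0]
    end = dates.iloc[-1]
    if start.dayofyear != 1 or (end.month, end.day) != (12, 31):
        raise ValueError("forcing must span whole calendar years "
                         f"(got {start.date()}..{end.date()})")
    expected = pd.date_range(start, end, freq="D")
    if len(expected) != len(dates) or not (expected == dates.values).all():
        missing = expected.difference(pd.DatetimeIndex(dates))
        shown = ", ".join(str(d.date()) for d in missing[:5])
        raise ValueError(f"gaps in forcing; missing dates include: {shown}")


def simulate_site(forcing: pd.DataFrame, ai: float,
                  constants: ModelConstants = DEFAULT_CONSTANTS,
                  spin_up: bool = True) -> LAITrajectory:
    """Run the prognostic LAI model over a daily forcing table.

    Parameters
    ----------
    forcing:
        Daily forcing covering one or more whole calendar years, no gaps
        (columns as in :mod:`prolai.forcing`).
    ai:
        Climatological aridity index of the site (> 0).
    constants:
        Model parameters.
    spin_up:
        If True (default), the first year is simulated once beforehand to
        initialise the EMA memory and discarded from the output; otherwise
        LAI_sim on day 1 equals that day's steady state.
    """
    if not ai > 0:
        raise ValueError("ai must be > 0")
    forcing = forcing.reset_index(drop=True)
    _check_complete_years(forcing["date"])
    dates = pd.to_datetime(forcing["date"])

    a0_all = potential_gpp_series(
        forcing["tair_c"].to_numpy(dtype=float),
        forcing["ppfd_mol_m2_d"].to_numpy(dtype=float),
        forcing["vpd_pa"].to_numpy(dtype=float),
        forcing["co2_ppm"].to_numpy(dtype=float),
        forcing["patm_pa"].to_numpy(dtype=float),
        constants=constants,
    )

    years = dates.dt.year
    ls_all = np.zeros(len(forcing))
    annual_rows = []
    year_list = sorted(years.unique())
    for yr in year_list:
        mask = (years == yr).to_numpy()
        drv = annual_drivers(forcing.loc[mask], ai, constants,
                             a0=a0_all[mask])
        lim = canopy_limits(drv, constants)
        m = m_from_drivers(drv, lim, constants.sigma)
        mu = m * a0_all[mask]
        unc = np.asarray(uncapped_steady_state_lai(mu, constants.k))
        ls_all[mask] = np.minimum(unc, lim.lai_max)
        annual_rows.append({
            "year": int(yr),
            "a0sum_gc": drv.a0sum_gc,
            "precip_mm": drv.precip_mol / MM_PRECIP_TO_MOL,
            "gsl_days": drv.gsl,
            "d_gs_pa": drv.d_gs,
            "f0": lim.f0,
            "fapar_max": lim.fapar_max,
            "lai_max": lim.lai_max,
            "limitation": lim.limitation,
            "m": m,
        })

    alpha = constants.alpha
    first_mask = (years == year_list[0]).to_numpy()
    if spin_up:
        # one pass over the first year to initialise the EMA memory
        prev = float(ls_all[first_mask][0])
        for ls in ls_all[first_mask]:
            prev = ema_update(prev, float(ls), alpha)
    else:
        prev = float(ls_all[0])

    lai_sim = np.empty(len(forcing))
    for i, ls in enumerate(ls_all):
        if i == 0 and not spin_up:
            lai_sim[0] = prev
            continue
        prev = ema_update(prev, float(ls), alpha)
        lai_sim[i] = prev
    if not spin_up:
        lai_sim[0] = float(ls_all[0])

    daily = pd.DataFrame({
        "date": dates,
        "a0_gc_m2_d": a0_all,
        "ls": ls_all,
        "lai_sim": lai_sim,
    })
    annual = pd.DataFrame(annual_rows)
    return LAITrajectory(daily=daily, annual=annual)
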