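"""Site forcing: CSV I/O and a synthetic daily-meteorology generator.

The generator emulates the statistical structure of FLUXNET-style daily
series for a single mid-latitude site: annual sinusoids in temperature,
PPFD and VPD (peaking mid-year, northern-hemisphere convention) with
additive Gaussian noise, and precipitation as Bernoulli wet days with
exponentially distributed amounts scaled so the expected annual total
matches a prescribed value. CO₂ and pressure are held constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

FORCING_COLUMNS = ["date", "tair_c", "ppfd_mol_m2_d", "vpd_pa", "co2_ppm",
                   "patm_pa", "precip_mm"]


@dataclass(frozen=True)
class SyntheticForcingSpec:
    """Parameters of the synthetic forcing generator.

    Defaults describe a humid temperate site: mean temperature 10 °C with a
    12 °C seasonal amplitude, PPFD 25 ± 15 mol m⁻² d⁻¹, VPD 800 ± 500 Pa,
    800 mm yr⁻¹ of rain on ~30% of days.
    """

    years: int = 2
    start_year: int = 2001
    tair_mean: float = 10.0      # °C
    tair_amp: float = 12.0       # °C, sinusoid amplitude
    ppfd_mean: float = 25.0      # mol m⁻² d⁻¹
    ppfd_amp: float = 15.0
    vpd_mean: float = 800.0      # Pa
    vpd_amp: float = 500.0
    co2_ppm: float = 400.0
    patm_pa: float = 101325.0
    precip_annual_mm: float = 800.0
    wet_day_prob: float = 0.3
    tair_noise_sd: float = 1.5
    ppfd_noise_sd: float = 3.0
    vpd_noise_sd: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        for name in ("tair_amp", "ppfd_amp", "vpd_amp", "tair_noise_sd",
                     "ppfd_noise_sd", "vpd_noise_sd", "precip_annual_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.wet_day_prob <= 1:
            raise ValueError("wet_day_prob must lie in [0, 1]")
        if self.co2_ppm <= 0 or self.patm_pa <= 0:
            raise ValueError("co2_ppm and patm_pa must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticForcingSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown spec fields: {sorted(unknown)}")
        return cls(**d)


def _seasonal(doy: np.ndarray, ndays: np.ndarray, mean: float,
              amp: float) -> np.ndarray:
    # peak at mid-year (day ndays/2), northern-hemisphere convention
    return mean - amp * np.cos(2.0 * np.pi * doy / ndays)


def generate_forcing(spec: SyntheticForcingSpec) -> pd.DataFrame:
    """Generate a daily forcing table over whole calendar years.

    Returns a DataFrame with the standard forcing columns; fully
    reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(
        f"{spec.start_year}-01-01",
        f"{spec.start_year + spec.years - 1}-12-31",
        freq="D",
    )
    doy = dates.dayofyear.to_numpy(dtype=float) - 1.0
    ndays = np.where(dates.is_leap_year, 366.0, 365.0)
    n = len(dates)

    tair = _seasonal(doy, ndays, spec.tair_mean, spec.tair_amp)
    ppfd = _seasonal(doy, ndays, spec.ppfd_mean, spec.ppfd_amp)
    vpd = _seasonal(doy, ndays, spec.vpd_mean, spec.vpd_amp)
    if spec.tair_noise_sd > 0:
        tair = tair + rng.normal(0.0, spec.tair_noise_sd, n)
    if spec.ppfd_noise_sd > 0:
        ppfd = ppfd + rng.normal(0.0, spec.ppfd_noise_sd, n)
    if spec.vpd_noise_sd > 0:
        vpd = vpd + rng.normal(0.0, spec.vpd_noise_sd, n)
    ppfd = np.maximum(ppfd, 0.0)
    vpd = np.maximum(vpd, 0.0)

    precip = np.zeros(n)
    if spec.precip_annual_mm > 0 and spec.wet_day_prob > 0:
        wet = rng.random(n) < spec.wet_day_prob
        mean_amount = spec.precip_annual_mm / (365.25 * spec.wet_day_prob)
        precip[wet] = rng.exponential(mean_amount, wet.sum())

    return pd.DataFrame({
        "date": dates,
        "tair_c": tair,
        "ppfd_mol_m2_d": ppfd,
        "vpd_pa": vpd,
        "co2_ppm": spec.co2_ppm,
        "patm_pa": spec.patm_pa,
        "precip_mm": precip,
    })


def read_forcing_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a daily forcing CSV (comma-separated, UTF-8, ISO dates).

    Required columns: date, tair_c, ppfd_mol_m2_d, vpd_pa, co2_ppm,
    patm_pa, precip_mm, in any order; extra columns are ignored. The result
    is date-sorted and validated against the physical bounds of the forcing
    (non-negative PPFD/VPD/precipitation, positive CO₂ and pressure).
    """
    df = pd.read_csv(path)
    for col in FORCING_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date in {path}: {exc}") from exc
    if df["date"].duplicated().any():
        dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
        raise ValueError(f"duplicate date {dup.date()}")
    df = df[FORCING_COLUMNS].sort_values("date").reset_index(drop=True)
    _validate_forcing(df)
    return df


def write_forcing_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a forcing table in the standard CSV schema."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _validate_forcing(df: pd.DataFrame) -> None:
    num = df[FORCING_COLUMNS[1:]]
    if not np.isfinite(num.to_numpy(dtype=float)).all():
        bad = [c for c in num.columns
               if not np.isfinite(num[c].to_numpy(dtype=float)).all()]
        raise ValueError(f"non-finite values in columns {bad}")
    for col in ("ppfd_mol_m2_d", "vpd_pa", "precip_mm"):
        if (df[col] < 0).any():
            raise ValueError(f"negative values in column {col}")
    for col in ("co2_ppm", "patm_pa"):
        if (df[col] <= 0).any():
            raise ValueError(f"non-positive values in column {col}")


def aridity_index(pet_annual_mm, precip_annual_mm) -> float:
    """Climatological aridity index: mean annual PET over mean annual precip.

    Both arguments are per-year series over the same climatology window;
    the result is the ratio of the two means (not the mean of ratios).
    """
    pet = np.asarray(pet_annual_mm, dtype=float)
    pr = np.asarray(precip_annual_mm, dtype=float)
    if pet.size == 0 or pr.size == 0:
        raise ValueError("need at least one year of PET and precipitation")
    if not pr.mean() > 0:
        raise ValueError("mean precipitation must be > 0")
    return float(pet.mean() / pr.mean())
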