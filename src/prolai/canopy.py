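"""Seasonal maximum fAPAR and LAI from energy vs water limitation.

Two optimality arguments bound the canopy a site can sustain in a year:

* **energy limited** — leaves cost carbon (z per unit LAI per year); with
  Beer's-law shading the marginal leaf pays for itself only while
  fAPAR ≤ 1 − z/(k·A₀ₛᵤₘ), which maximises the net carbon profit
  A₀·fAPAR − z·LAI;
* **water limited** — the canopy can transpire at most a fraction f₀ of
  annual precipitation, and fixing carbon costs water in proportion to
  1.6·D/(c_a(1 − χ)), so fAPAR ≤ [c_a(1 − χ)/(1.6 D)]·f₀·P/A₀ₛᵤₘ.

The realised seasonal maximum is the lesser of the two; LAI_max follows by
inverting Beer's law. f₀ itself declines away from the energy/water
transition as f₀(AI) = f0max·exp(−b·ln²(AI/ai_opt)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, ModelConstants


@dataclass(frozen=True)
class AnnualDrivers:
    """Per-calendar-year aggregates driving the canopy limits.

    Growing-season ("gs") statistics are taken over days with tair above
    the frost threshold.
    """

    year: int
    a0sum_gc: float      # annual total potential GPP, g C m⁻² yr⁻¹
    a0sum_mol: float     # same, mol C m⁻² yr⁻¹
    precip_mol: float    # annual total precipitation, mol H₂O m⁻² yr⁻¹
    d_gs: float          # growing-season mean VPD, Pa
    chi_gs: float        # χ at growing-season mean conditions
    ca_gs: float         # growing-season mean ambient CO₂ partial pressure, Pa
    gsl: int             # growing season length, days
    ai: float            # climatological aridity index

    def __post_init__(self) -> None:
        if min(self.a0sum_gc, self.a0sum_mol, self.precip_mol) < 0:
            raise ValueError("annual sums must be >= 0")
        if not 0 <= self.gsl <= 366:
            raise ValueError("gsl must lie in [0, 366]")
        if not self.ai > 0:
            raise ValueError("ai must be > 0")


@dataclass(frozen=True)
class CanopyLimits:
    """Seasonal maximum canopy cover for one year."""

    fapar_max: float
    lai_max: float
    limitation: str      # "energy" | "water" | "none"
    f0: float


def f0_from_ai(
    ai: float,
    b: float = DEFAULT_CONSTANTS.b,
    f0max: float = DEFAULT_CONSTANTS.f0max,
    ai_opt: float = DEFAULT_CONSTANTS.ai_opt,
) -> float:
    """Fraction of annual precipitation transpired by the canopy.

    ``f0 = f0max · exp(−b · ln²(ai/ai_opt))``; peaks at ``f0max`` when
    ``ai == ai_opt`` and decays log-symmetrically on either side.
    """
    if not ai > 0:
        raise ValueError("ai must be > 0")
    return f0max * float(np.exp(-b * np.log(ai / ai_opt) ** 2))


def energy_limited_fapar(
    a0sum_mol: float,
    z: float = DEFAULT_CONSTANTS.z,
    k: float = DEFAULT_CONSTANTS.k,
) -> float:
    """Energy-limited fAPAR_max = max(0, 1 − z/(k·A₀ₛᵤₘ))."""
    if a0sum_mol < 0:
        raise ValueError("a0sum_mol must be >= 0")
    if a0sum_mol == 0:
        return 0.0
    return max(0.0, 1.0 - z / (k * a0sum_mol))


def water_limited_fapar(
    f0: float,
    precip_mol: float,
    a0sum_mol: float,
    ca_gs: float,
    chi_gs: float,
    d_gs: float,
) -> float:
    """Water-limited fAPAR_max = [c_a(1 − χ)/(1.6 D)] · f₀·P / A₀ₛᵤₘ.

    All quantities in mutually consistent units: ``ca_gs`` and ``d_gs`` in
    Pa, ``precip_mol`` and ``a0sum_mol`` in mol m⁻² yr⁻¹. The result is not
    yet capped; a zero ``a0sum_mol`` returns +inf (capped downstream).
    """
    if min(f0, precip_mol, a0sum_mol, ca_gs, d_gs) < 0 or chi_gs < 0:
        raise ValueError("water-branch inputs must be non-negative")
    if a0sum_mol == 0.0:
        return np.inf
    wue = ca_gs * (1.0 - chi_gs) / (1.6 * d_gs)
    return wue * f0 * precip_mol / a0sum_mol


def canopy_limits(
    drivers: AnnualDrivers,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> CanopyLimits:
    """Seasonal maximum fAPAR/LAI: min of energy and water branches.

    A year with no growing season (gsl = 0) supports no canopy. fAPAR_max is
    clamped to ``constants.fapar_cap`` so LAI_max stays finite; the
    ``limitation`` flag records which branch was binding ("none" when the
    canopy is zero).
    """
    f0 = f0_from_ai(drivers.ai, constants.b, constants.f0max,
                    constants.ai_opt)
    if drivers.gsl == 0:
        return CanopyLimits(0.0, 0.0, "none", f0)

    e_br = energy_limited_fapar(drivers.a0sum_mol, constants.z, constants.k)
    w_br = water_limited_fapar(f0, drivers.precip_mol, drivers.a0sum_mol,
                               drivers.ca_gs, drivers.chi_gs, drivers.d_gs)
    fapar = min(e_br, w_br)
    fapar = min(max(fapar, 0.0), constants.fapar_cap)
    if fapar == 0.0:
        limitation = "none"
    elif w_br < e_br:
        limitation = "water"
    else:
        limitation = "energy"
    lai_max = -np.log(1.0 - fapar) / constants.k
    return CanopyLimits(float(fapar), float(lai_max), limitation, float(f0))
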