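"""Model constants.

All tunable parameters of the LAI model live in a single frozen dataclass so
that a run is fully specified by (forcing, aridity index, ModelConstants).
Defaults are the model's global parameterisation: the canopy light
extinction coefficient k = 0.5, leaf cost z = 12.227 mol m⁻² a⁻¹, allocation
shape factor σ = 0.771, EMA smoothing α = 0.067 (≈ 15-day memory), and the
transpiration-fraction curve f₀(AI) = 0.65·exp(−0.604169·ln²(AI/1.9)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

#: g C per mol C
C_MOLMASS = 12.011
#: mol H2O per mm of precipitation over 1 m² (1 kg m⁻² / 18.015 g mol⁻¹)
MM_PRECIP_TO_MOL = 1000.0 / 18.015

# Temperature/pressure response coefficients of the photosynthesis
# intermediates (Bernacchi-type Arrhenius responses referenced to 25 °C and
# standard pressure).
GAMMASTAR25_PA = 4.332      # CO2 compensation point at 25 °C, 101325 Pa
GAMMASTAR_DHA = 37830.0     # J mol⁻¹
KC25_PA = 39.97             # Michaelis constant for CO2 at 25 °C
KC_DHA = 79430.0
KO25_PA = 27480.0           # Michaelis constant for O2 at 25 °C
KO_DHA = 36380.0
O2_MOLFRAC = 0.209476       # mole fraction of O2 in dry air
R_GAS = 8.3145              # J mol⁻¹ K⁻¹


@dataclass(frozen=True)
class ModelConstants:
    """Parameters of the prognostic LAI model.

    Attributes
    ----------
    k:
        Canopy light extinction coefficient of Beer's law (dimensionless).
    z:
        Unit cost of constructing and maintaining leaves in the net carbon
        profit criterion, mol m⁻² a⁻¹.
    sigma:
        Shape factor expressing how far the seasonal LAI course departs from
        a square wave at LAI_max (dimensionless).
    alpha:
        EMA smoothing factor in (0, 1]; memory length ≈ 1/alpha days.
    beta:
        Unit cost ratio of carboxylation vs transpiration capacity at 25 °C.
    cstar:
        Cost of maintaining electron transport capacity (dimensionless);
        enters the light-use-efficiency Jmax limitation term.
    phi0:
        Intrinsic quantum yield, mol C mol⁻¹ photon. Held constant.
    b, f0max, ai_opt:
        Parameters of the transpiration-fraction curve
        f₀(AI) = f0max·exp(−b·ln²(AI/ai_opt)).
    fapar_cap:
        Upper cap on fAPAR_max; keeps LAI_max finite.
    vpd_floor:
        Minimum VPD (Pa) applied before any use of D.
    tair_frost:
        Daily mean temperature (°C) at or below which potential GPP is zero
        and the day does not count toward the growing season.
    """

    k: float = 0.5
    z: float = 12.227
    sigma: float = 0.771
    alpha: float = 0.067
    beta: float = 146.0
    cstar: float = 0.41
    phi0: float = 0.05
    b: float = 0.604169
    f0max: float = 0.65
    ai_opt: float = 1.9
    fapar_cap: float = 1.0 - 1e-4
    vpd_floor: float = 10.0
    tair_frost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k", "z", "sigma", "beta", "cstar", "phi0", "b",
                     "f0max", "ai_opt", "vpd_floor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.fapar_cap < 1:
            raise ValueError("fapar_cap must lie in (0, 1)")

    def with_updates(self, **kwargs: Any) -> "ModelConstants":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = ModelConstants()
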