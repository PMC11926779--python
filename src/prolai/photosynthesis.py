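"""Daily light-use efficiency and potential GPP (the P model).

The P model predicts gross primary production as
``A = fAPAR × LUE × PPFD`` where the light use efficiency follows from
eco-evolutionary optimality: stomata adjust the ratio χ of leaf-internal to
ambient CO₂ partial pressure to balance the carbon cost of transpiration
against that of carboxylation, and electron transport capacity is limited so
that marginal gains equal a fixed cost c*.

Potential GPP A₀ is the GPP a canopy would achieve at fAPAR = 1; it is the
sole daily driver of the LAI model downstream.

Functions accept scalars or numpy arrays (broadcasting applies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .constants import (
    C_MOLMASS,
    GAMMASTAR25_PA,
    GAMMASTAR_DHA,
    KC25_PA,
    KC_DHA,
    KO25_PA,
    KO_DHA,
    O2_MOLFRAC,
    R_GAS,
    DEFAULT_CONSTANTS,
    ModelConstants,
)

ArrayLike = Union[float, np.ndarray]

TK25 = 298.15
P0 = 101325.0


@dataclass(frozen=True)
class DailyForcing:
    """One day of meteorological drivers for a site.

    ``soilm_mult`` is an optional dimensionless multiplier in [0, 1] applied
    to potential GPP; it is a hook for an externally computed soil-moisture
    stress factor and defaults to 1 (no stress).
    """

    date: object
    tair: float          # daily mean air temperature, °C
    ppfd: float          # incident PPFD, mol photons m⁻² d⁻¹
    vpd: float           # vapor pressure deficit, Pa
    co2: float           # ambient CO₂ mole fraction, ppm
    patm: float          # atmospheric pressure, Pa
    precip: float        # precipitation, mm d⁻¹
    soilm_mult: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tair", "ppfd", "vpd", "co2", "patm", "precip",
                     "soilm_mult"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for {name!r}")
        if self.ppfd < 0:
            raise ValueError("ppfd must be >= 0")
        if self.vpd < 0:
            raise ValueError("vpd must be >= 0")
        if self.co2 <= 0:
            raise ValueError("co2 must be > 0")
        if self.patm <= 0:
            raise ValueError("patm must be > 0")
        if self.precip < 0:
            raise ValueError("precip must be >= 0")
        if not 0 <= self.soilm_mult <= 1:
            raise ValueError("soilm_mult must lie in [0, 1]")


@dataclass(frozen=True)
class PhotoEnv:
    """Temperature/pressure-dependent photosynthesis intermediates."""

    gammastar: ArrayLike   # CO₂ compensation point Γ*, Pa
    kmm: ArrayLike         # effective Michaelis–Menten coefficient K, Pa
    eta_star: ArrayLike    # relative viscosity of water η*
    ca: ArrayLike          # ambient CO₂ partial pressure, Pa
    chi: ArrayLike         # optimal ci/ca ratio
    m_term: ArrayLike      # CO₂ limitation term m
    lue: ArrayLike         # light use efficiency, g C mol⁻¹ photon


def _arrhenius(k25: float, dha: float, tk: ArrayLike) -> ArrayLike:
    return k25 * np.exp(dha * (tk - TK25) / (TK25 * R_GAS * tk))


def gammastar(tair: ArrayLike, patm: ArrayLike) -> ArrayLike:
    """Photorespiratory CO₂ compensation point Γ* (Pa)."""
    tk = np.asarray(tair, dtype=float) + 273.15
    return _arrhenius(GAMMASTAR25_PA, GAMMASTAR_DHA, tk) * (
        np.asarray(patm, dtype=float) / P0
    )


def kmm(tair: ArrayLike, patm: ArrayLike) -> ArrayLike:
    """Effective Michaelis–Menten coefficient K = Kc(1 + pO₂/Ko) (Pa)."""
    tk = np.asarray(tair, dtype=float) + 273.15
    kc = _arrhenius(KC25_PA, KC_DHA, tk)
    ko = _arrhenius(KO25_PA, KO_DHA, tk)
    po2 = O2_MOLFRAC * np.asarray(patm, dtype=float)
    return kc * (1.0 + po2 / ko)


def water_density(tair: ArrayLike, patm: ArrayLike) -> ArrayLike:
    """Density of liquid water (kg m⁻³), Tumlirz equation of state."""
    tc = np.asarray(tair, dtype=float)
    pbar = np.asarray(patm, dtype=float) * 1e-5  # Pa -> bar

    lam = 1788.316 + 21.55053 * tc - 0.4695911 * tc**2 \
        + 3.096363e-3 * tc**3 - 7.341182e-6 * tc**4
    po = 5918.499 + 58.05267 * tc - 1.1253317 * tc**2 \
        + 6.6123869e-3 * tc**3 - 1.4661625e-5 * tc**4
    vinf = 0.6980547 - 7.435626e-4 * tc + 3.704258e-5 * tc**2 \
        - 6.315724e-7 * tc**3 + 9.829576e-9 * tc**4 \
        - 1.197269e-10 * tc**5 + 1.005461e-12 * tc**6 \
        - 5.437898e-15 * tc**7 + 1.69946e-17 * tc**8 \
        - 2.295063e-20 * tc**9

    v = vinf + lam / (po + pbar)      # specific volume, cm³ g⁻¹
    return 1e3 / v


def water_viscosity(tair: ArrayLike, patm: ArrayLike) -> ArrayLike:
    """Dynamic viscosity of liquid water (Pa s), Huber et al. formulation."""
    tbar = (np.asarray(tair, dtype=float) + 273.15) / 647.096
    rbar = water_density(tair, patm) / 322.0

    # viscosity in the dilute-gas limit
    mu0 = 1.67752 + 2.20462 / tbar + 0.6366564 / tbar**2 - 0.241605 / tbar**3
    mu0 = 100.0 * np.sqrt(tbar) / mu0

    # h[j, i]: j indexes powers of (ρ̄ − 1), i indexes powers of (1/T̄ − 1)
    h = np.array([
        [0.520094, 0.0850895, -1.08374, -0.289555, 0.0, 0.0],
        [0.222531, 0.999115, 1.88797, 1.26613, 0.0, 0.120573],
        [-0.281378, -0.906851, -0.772479, -0.489837, -0.25704, 0.0],
        [0.161913, 0.257399, 0.0, 0.0, 0.0, 0.0],
        [-0.0325372, 0.0, 0.0, 0.0698452, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.00872102, 0.0],
        [0.0, 0.0, 0.0, -0.00435673, 0.0, -0.000593264],
    ])
    ctbar = (1.0 / tbar) - 1.0
    mu1 = np.zeros_like(np.asarray(tbar, dtype=float))
    for i in range(6):
        coef = np.zeros_like(mu1)
        for j in range(7):
            coef = coef + h[j, i] * (rbar - 1.0) ** j
        mu1 = mu1 + ctbar**i * coef
    mu1 = np.exp(rbar * mu1)

    return mu0 * mu1 * 1e-6  # µPa s -> Pa s


def eta_star(tair: ArrayLike, patm: ArrayLike) -> ArrayLike:
    """Viscosity of water relative to its value at 25 °C, standard pressure."""
    return water_viscosity(tair, patm) / water_viscosity(25.0, P0)


def photo_env(
    tair: ArrayLike,
    vpd: ArrayLike,
    co2: ArrayLike,
    patm: ArrayLike,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> PhotoEnv:
    """Evaluate the P-model photosynthetic environment for one day.

    Computes Γ*, K and η* from temperature and pressure, the optimal
    χ = Γ*/ca + (1 − Γ*/ca)·ξ/(ξ + √D) with ξ = √(β(K + Γ*)/(1.6 η*)),
    the CO₂ limitation term m = (ci − Γ*)/(ci + 2Γ*) at ci = χ·ca, and the
    light use efficiency φ₀·m·√(1 − (c*/m)^(2/3)) converted to g C per mol
    photons. VPD is floored at ``constants.vpd_floor``.

    Raises
    ------
    ValueError
        On non-finite inputs or air temperature outside [−40, 60] °C.
    """
    tair = np.asarray(tair, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    patm = np.asarray(patm, dtype=float)
    for name, v in (("tair", tair), ("vpd", vpd), ("co2", co2),
                    ("patm", patm)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value for {name!r}")
    if np.any(tair < -40.0) or np.any(tair > 60.0):
        raise ValueError("tair outside the supported range [-40, 60] °C")

    d = np.maximum(vpd, constants.vpd_floor)
    gs = gammastar(tair, patm)
    k = kmm(tair, patm)
    ns = eta_star(tair, patm)
    ca = co2 * 1e-6 * patm

    xi = np.sqrt(constants.beta * (k + gs) / (1.6 * ns))
    chi = gs / ca + (1.0 - gs / ca) * xi / (xi + np.sqrt(d))
    ci = chi * ca
    m = (ci - gs) / (ci + 2.0 * gs)

    # Jmax limitation: LUE real-valued only for m > c*; zero otherwise.
    ratio = np.clip(constants.cstar / np.maximum(m, 1e-12), 0.0, None)
    inner = 1.0 - ratio ** (2.0 / 3.0)
    mprime = np.where(inner > 0.0, m * np.sqrt(np.maximum(inner, 0.0)), 0.0)

    lue = constants.phi0 * mprime * C_MOLMASS
    return PhotoEnv(gammastar=gs, kmm=k, eta_star=ns, ca=ca, chi=chi,
                    m_term=m, lue=lue)


def potential_gpp(
    f: DailyForcing,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Potential GPP A₀ (g C m⁻² d⁻¹): LUE × PPFD × soil multiplier.

    Days with mean temperature at or below ``constants.tair_frost`` (0 °C by
    default) are assigned zero assimilation, consistent with the
    growing-season definition used for the annual drivers.
    """
    if f.tair <= constants.tair_frost:
        return 0.0
    env = photo_env(f.tair, f.vpd, f.co2, f.patm, constants)
    return float(env.lue) * f.ppfd * f.soilm_mult


def potential_gpp_series(
    tair: np.ndarray,
    ppfd: np.ndarray,
    vpd: np.ndarray,
    co2: np.ndarray,
    patm: np.ndarray,
    soilm_mult: Optional[np.ndarray] = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Vectorised daily A₀ over aligned arrays (g C m⁻² d⁻¹)."""
    env = photo_env(tair, vpd, co2, patm, constants)
    a0 = np.asarray(env.lue) * np.asarray(ppfd, dtype=float)
    if soilm_mult is not None:
        a0 = a0 * np.asarray(soilm_mult, dtype=float)
    return np.where(np.asarray(tair, dtype=float) > constants.tair_frost,
                    a0, 0.0)
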