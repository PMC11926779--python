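"""Steady-state LAI and GPP: the coupled Beer's-law/allocation fixed point.

Under constant weather the canopy settles at the LAI where the leaf area
supported by allocation matches the light it absorbs:

    L_s = m · A_s,        A_s = A₀ (1 − e^{−k L_s}),

i.e. ``L = μ (1 − e^{−kL})`` with μ = m·A₀. Besides the trivial root L = 0,
a positive root exists iff kμ > 1, and it has the closed form

    L_s = μ + (1/k) · W₀(−kμ e^{−kμ}),

with W₀ the principal branch of the Lambert W function. The result is capped
at the year's LAI_max.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import lambertw

from .constants import DEFAULT_CONSTANTS

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class SteadyState:
    ls: ArrayLike        # steady-state LAI, m² m⁻²
    as_gpp: ArrayLike    # steady-state GPP, g C m⁻² d⁻¹
    mu: ArrayLike        # m·A₀, m² m⁻²
    capped: ArrayLike    # True where LAI_max was binding


def uncapped_steady_state_lai(mu: ArrayLike,
                              k: float = DEFAULT_CONSTANTS.k) -> ArrayLike:
    """Positive fixed point of L = μ(1 − e^{−kL}); 0 where kμ ≤ 1.

    The W₀ argument −kμ·e^{−kμ} lies in [−1/e, 0] for all μ ≥ 0; rounding
    can push it marginally below −1/e, so it is clamped there.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be >= 0")
    kmu = k * mu
    arg = np.clip(-kmu * np.exp(-kmu), -1.0 / np.e, 0.0)
    w = np.real(lambertw(arg, k=0))
    ls = mu + w / k
    # For kμ ≤ 1 the identity W₀(−x e^{−x}) = −x makes the expression
    # collapse to the trivial root; enforce it exactly.
    ls = np.where(kmu <= 1.0, 0.0, np.maximum(ls, 0.0))
    return ls if ls.ndim else float(ls)


def steady_state_gpp(a0: ArrayLike, ls: ArrayLike,
                     k: float = DEFAULT_CONSTANTS.k) -> ArrayLike:
    """Steady-state GPP A_s = A₀(1 − e^{−k·L_s}), g C m⁻² d⁻¹."""
    a0 = np.asarray(a0, dtype=float)
    ls = np.asarray(ls, dtype=float)
    out = a0 * (1.0 - np.exp(-k * ls))
    return out if out.ndim else float(out)


def steady_state_lai(
    mu: ArrayLike,
    k: float = DEFAULT_CONSTANTS.k,
    lai_max: ArrayLike = np.inf,
    a0: ArrayLike = 0.0,
) -> SteadyState:
    """Solve the daily steady state and cap at LAI_max.

    Parameters
    ----------
    mu:
        Allocation ratio times potential GPP, m² m⁻² (≥ 0).
    k:
        Light extinction coefficient.
    lai_max:
        Seasonal cap on LAI (≥ 0).
    a0:
        Potential GPP of the day, used only to report ``as_gpp``.
    """
    lai_max = np.asarray(lai_max, dtype=float)
    if np.any(lai_max < 0):
        raise ValueError("lai_max must be >= 0")
    unc = np.asarray(uncapped_steady_state_lai(mu, k))
    ls = np.minimum(unc, lai_max)
    capped = unc > lai_max
    scalar = ls.ndim == 0
    asg = steady_state_gpp(a0, ls, k)
    return SteadyState(
        ls=float(ls) if scalar else ls,
        as_gpp=asg,
        mu=float(np.asarray(mu, dtype=float)) if scalar else np.asarray(mu, dtype=float),
        capped=bool(capped) if scalar else capped,
    )
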