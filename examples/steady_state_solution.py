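"""The Lambert-W steady state of the coupled GPP-LAI system.

The steady-state LAI solves L = mu (1 - e^{-kL}) with mu = m * A0. Below
the threshold k*mu = 1 only the bare-ground solution exists; above it the
closed form mu + W0(-k mu e^{-k mu})/k gives the vegetated fixed point,
here verified against plain bisection.
"""

import math

from prolai import steady_state_lai

k = 0.5


def bisect(mu, lo=1e-9, hi=1e4):
    f = lambda L: mu * (1 - math.exp(-k * L)) - L
    if f(lo) <= 0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if f(mid) > 0 else (lo, mid)
    return 0.5 * (lo + hi)


print(f"{'mu':>6} {'k*mu':>6} {'L_s (Lambert W)':>16} {'L_s (bisection)':>16}")
for mu in (0.5, 2.0, 2.5, 4.0, 8.0, 20.0):
    ls = steady_state_lai(mu, k=k, lai_max=10.0).ls
    print(f"{mu:6.2f} {k * mu:6.2f} {ls:16.8f} {min(bisect(mu), 10.0):16.8f}")

print("\nk*mu <= 1 collapses to L_s = 0 (allocation cannot pay for a "
      "canopy); above it L_s rises continuously and saturates toward mu.")
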