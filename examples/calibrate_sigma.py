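"""Calibrate the allocation shape factor sigma from site-year data.

sigma links the observed allocation ratio m = mean(LAI)/mean(GPP) to annual
aggregates via m = sigma * GSL * LAI_max / (A0sum * fAPAR_max). Here we
build 200 synthetic site-years obeying that relation with sigma = 0.771 and
5% noise, then recover sigma by least squares through the origin.
"""

import numpy as np

from prolai import fit_sigma

rng = np.random.default_rng(7)
sigma_true = 0.771
site_years = []
for _ in range(200):
    gsl = float(rng.integers(60, 360))
    lai_max = float(rng.uniform(0.5, 6.0))
    a0sum = float(rng.uniform(500, 4000))
    fapar_max = float(rng.uniform(0.2, 0.95))
    m = sigma_true * gsl * lai_max / (a0sum * fapar_max)
    m *= 1.0 + 0.05 * float(rng.standard_normal())
    site_years.append((m, gsl, lai_max, a0sum, fapar_max))

sigma_hat = fit_sigma(site_years)
print(f"true sigma      : {sigma_true}")
print(f"fitted sigma    : {sigma_hat:.4f}")
print(f"relative error  : {abs(sigma_hat / sigma_true - 1) * 100:.2f}%")
print("\nWith noiseless data the through-origin fit recovers sigma "
      "exactly; 5% observation noise leaves it within a couple percent.")
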