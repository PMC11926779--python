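# prolai

A prognostic model of daily leaf area index (LAI) for terrestrial
ecosystems, driven only by daily meteorology and a climatological aridity
index. It is aimed at ecosystem modellers and land-surface scientists who
want seasonal-to-decadal leaf phenology predicted from first principles —
no satellite greenness inputs, no per-biome tuning — and at anyone who
needs a clean reference implementation of the underlying optimality
building blocks.

## The model

Four pieces chain together:

1. **Potential GPP (P model).** Daily gross primary production at full
   canopy cover, A₀ = LUE × PPFD, with light use efficiency
   LUE = φ₀·m·√(1 − (c*/m)^(2/3)) and
   m = (c_a − Γ\*)/(c_a + 2Γ\* + 3Γ\*·√(1.6 η\* D/(β(K + Γ\*)))).
   The ratio χ = c_i/c_a follows the least-cost optimality solution
   χ = Γ\*/c_a + (1 − Γ\*/c_a)·ξ/(ξ + √D), ξ = √(β(K + Γ\*)/(1.6 η\*)).
   Days with mean air temperature ≤ 0 °C fix no carbon.

2. **Seasonal maximum canopy (energy vs water limitation).** Per year,

   fAPAR_max = min[ 1 − z/(k·A₀ₛᵤₘ),  (c_a(1 − χ)/(1.6 D))·f₀·P/A₀ₛᵤₘ ],
   LAI_max = −ln(1 − fAPAR_max)/k,

   the energy branch maximising net carbon profit A₀·fAPAR − z·LAI, the
   water branch spending a fraction f₀(AI) = 0.65·exp(−0.604169·ln²(AI/1.9))
   of annual precipitation P on transpiration.

3. **Steady-state LAI (Lambert W).** With allocation ratio
   m = σ·GSL·LAI_max/(A₀ₛᵤₘ·fAPAR_max), each day's steady state solves
   L = μ(1 − e^(−kL)) with μ = m·A₀:

   L_s = min[ μ + (1/k)·W₀(−kμ·e^(−kμ)),  LAI_max ],

   which is exactly 0 while kμ ≤ 1.

4. **Acclimation lag (EMA).** The simulated actual LAI is
   LAI_sim(t) = α·L_s(t) + (1 − α)·LAI_sim(t − 1), with α = 0.067
   (≈ 15 days of memory) by default.

Default parameters: k = 0.5, z = 12.227 mol m⁻² a⁻¹, σ = 0.771, α = 0.067,
β = 146, c* = 0.41, φ₀ = 0.05 mol C mol⁻¹ photon.

## Worked example

```python
from prolai import SyntheticForcingSpec, generate_forcing, simulate_site

forcing = generate_forcing(SyntheticForcingSpec(years=3, seed=42))
traj = simulate_site(forcing, ai=1.2)
print(traj.annual.round(3).to_string(index=False))
```

prints

```
 year  a0sum_gc  precip_mm  gsl_days  d_gs_pa    f0  fapar_max  lai_max limitation     m
 2001  2157.927    689.258       280  906.776 0.572      0.864    3.989     energy 0.462
 2002  2131.072    713.982       281  900.547 0.572      0.862    3.964     energy 0.467
 2003  2177.786    803.981       273  894.689 0.572      0.865    4.007     energy 0.448
```

For this humid temperate site (AI = 1.2) the canopy is energy-limited:
annual potential GPP around 2150 g C m⁻² supports fAPAR_max ≈ 0.86, i.e. a
peak LAI near 4. `traj.daily` carries the date, daily potential GPP
`a0_gc_m2_d`, steady-state LAI `ls`, and the lagged `lai_sim` that an LAI
sensor would see. The same run from a shell:

```sh
prolai synth --out forcing.csv --seed 42
prolai run forcing.csv --ai 1.2 --out sim.csv          # + sim_annual.csv
prolai eval sim.csv reference.csv --level 7day         # skill report JSON
```

The `examples/` directory has one short script per capability
(site simulation, the aridity sweep of canopy limits, the Lambert-W steady
state vs bisection, σ calibration, skill evaluation), each printing the
numbers it computes and what they mean.

## Scope

The package is grid-agnostic and site-oriented: it reads daily forcing CSVs
(or generates synthetic forcing) and produces daily/annual CSV output.
Sub-daily photosynthetic acclimation, internal soil-moisture and PET
models, and satellite-data ingestion are out of scope; an externally
computed soil-moisture multiplier and PET series can be supplied.
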