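# Methods

## Model structure and assumptions

`prolai` predicts daily leaf area index by composing four optimality-based
components. The guiding assumptions are: (i) canopy carbon uptake follows a
light-use-efficiency form in which stomatal behaviour and electron
transport are co-optimised (the P model); (ii) on annual timescales the
maximum supportable canopy is set by whichever is scarcer, energy (carbon
profit net of leaf costs) or water (a transpirable fraction of annual
precipitation); (iii) if weather were held constant, LAI and GPP would
settle into a mutually consistent steady state in which a fixed fraction m
of GPP sustains leaf area; and (iv) real canopies track that steady state
with a first-order lag of a couple of weeks, represented by an exponential
moving average.

### Photosynthesis

Potential GPP is A₀ = LUE·PPFD on days above 0 °C and zero otherwise.
The frozen-day cutoff matches the growing-season definition used in the
annual aggregation and compensates for holding the quantum yield φ₀
constant (no cold inhibition) — without it, bright sub-zero days would fix
carbon. LUE uses the CO₂ limitation term m evaluated at the optimal
χ (least-cost balance of transpiration against carboxylation) and the
electron-transport limitation √(1 − (c*/m)^(2/3)); LUE is set to zero in
the (physically extreme) region m ≤ c* where that factor is undefined.

Temperature and pressure responses of the intermediates use the standard
forms of the P-model literature: Arrhenius responses for Γ* (4.332 Pa at
25 °C, ΔHa = 37830 J mol⁻¹) and the Michaelis constants
(Kc: 39.97 Pa, 79430 J mol⁻¹; Ko: 27480 Pa, 36380 J mol⁻¹; O₂ partial
pressure 0.209476·p_atm), and the Huber et al. viscosity of water over the
Tumlirz density for η*. These are implementation choices the headline
model is insensitive to at the few-percent level; coefficients live in
`constants.py`.

### Canopy limits

The energy branch 1 − z/(k·A₀ₛᵤₘ) and water branch
(c_a(1 − χ)/(1.6D))·f₀·P/A₀ₛᵤₘ are evaluated per calendar year in mol
units (precipitation mm × 55.51 → mol H₂O m⁻²; A₀ g C ÷ 12.011 → mol C).
D, χ and c_a in the water branch are all evaluated at growing-season mean
conditions (days above 0 °C); the averaging window for χ is a design
choice — using the same window as D keeps the branch's water-use
efficiency internally consistent. fAPAR_max is capped at 1 − 10⁻⁴
(LAI_max ≈ 18.4) purely to keep the Beer's-law inversion finite; a year
with no qualifying growing season gets fAPAR_max = LAI_max = 0.

z and σ ship as the global constants 12.227 mol m⁻² a⁻¹ and 0.771 and are
not refit here (refitting z requires global satellite data); a σ
calibration utility (`fit_sigma`) is provided for users with their own
site-year tables.

### Steady state

L = μ(1 − e^(−kL)) always admits L = 0; for kμ > 1 there is additionally a
positive root, which is the one used — the bare-ground root is an unstable
equilibrium there and ecologically trivial. The closed form
μ + W₀(−kμ·e^(−kμ))/k returns exactly that root on the principal branch;
its argument lies in [−1/e, 0] for all μ ≥ 0 and is clamped at −1/e
against floating-point underflow. For kμ ≤ 1 the expression collapses to
the trivial root via the identity W₀(−xe^(−x)) = −x (x ≤ 1) and the solver
returns exactly 0.0 rather than a rounding-level residual. The LAI_max cap
is applied after solving, as the outer min of the closed form.

### Lag filter

α maps to a memory length of τ ≈ 1/α days; `alpha_from_memory_days`
rounds to 3 decimals, so the commonly used pairs run
(3, 0.333) … (60, 0.0167). The EMA state persists across year boundaries.
Initialisation is a genuine open choice: by default the first forcing year
is simulated once as spin-up and discarded, which with a 15-day memory is
conservative; with `spin_up=False`, day 1 starts at its own steady state.

### Allocation ratio and σ fitting

GSL is the *longest single* run of consecutive days above 0 °C, counted
only if longer than 5 days — "the continuous period" is read as singular,
with the 5-day clause a qualification threshold, matching the square-wave
picture of one growing season. m = σ·GSL·LAI_max/(A₀ₛᵤₘ·fAPAR_max) uses
A₀ₛᵤₘ in g C m⁻² yr⁻¹ so that μ = m·A₀(daily) carries LAI units; m is
constant within a calendar year and zero in dormant years. σ is fitted by
ordinary least squares through the origin of observed m on the regressor
GSL·LAI_max/(A₀ₛᵤₘ·fAPAR_max) — the minimal criterion, exact in the
noiseless case and a simple ratio for a single site-year.

## Synthetic forcing

The generator emulates a single mid-latitude FLUXNET-style site: annual
sinusoids (peak at mid-year, northern-hemisphere convention) in
temperature, PPFD and VPD with additive Gaussian noise, constant CO₂ and
pressure, and precipitation as Bernoulli wet days with exponential
amounts calibrated so the expected annual total hits the prescribed value.
Defaults describe a humid temperate climate: 10 ± 12 °C, 25 ± 15 mol
photons m⁻² d⁻¹, 800 ± 500 Pa VPD, 800 mm yr⁻¹ on 30 % of days, noise
standard deviations 1.5 °C, 3 mol m⁻² d⁻¹ and 150 Pa. It does **not**
emulate weather autocorrelation, droughts, covariance between VPD and
temperature, interannual trends, or Southern-Hemisphere seasonality — so
passing tests demonstrate the numerical and structural correctness of the
model chain, not skill against real-world LAI observations, which requires
real forcing and satellite benchmarks outside this package's scope.

## Numerical choices

- VPD is floored at 10 Pa everywhere before use, preventing blow-up of
  ξ/(ξ + √D) and of the 1.6·D denominator of the water branch.
- Air temperature outside [−40, 60] °C is rejected rather than
  extrapolated.
- Solver agreement tolerances in the tests: 10⁻⁸ against bisection and
  damped fixed-point iteration; Beer's-law round trips to 10⁻¹²;
  end-to-end repeat-run agreement to 10⁻¹².
- Aggregation: 7-day blocks are anchored at 1 January of each year (the
  final 1–2 day block is kept); monthly means pool by month of year;
  "spatial" means are multi-year means per site. R² is the squared Pearson
  correlation, reported alongside the regression slope of simulated on
  observed.
- Problem sizes in tests and examples (1000-instance solver sweeps,
  200 site-years for σ, 2–3 year simulations) are chosen as the smallest
  sizes at which the checked properties are sharp.

## Limitations

- No sub-daily acclimation of photosynthesis; φ₀ is constant, with no
  temperature dependence.
- Soil moisture enters only through an optional user-supplied daily
  multiplier on A₀; there is no internal soil-water or PET model (the
  aridity index is a user input or computed from a user PET series).
- C₄ photosynthesis, biome-specific σ or k, carry-over mechanisms
  (soil-moisture memory, stored carbohydrates) and gridded raster
  pipelines are out of scope; the core is grid-agnostic and can be mapped
  over pixels by the caller.
- Annual drivers for year Y use year Y's own forcing, so the model as
  shipped is diagnostic-prognostic for complete years, not a forecast of a
  partially observed year.
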