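# Methods

This note documents the models inside `pmadjoint`: the toy chemical-transport
model and its discrete adjoint, the satellite fusion and health-impact chain
that define the cost function, the synthetic world the pipeline runs on, the
numerical choices, and what the package's passing tests do and do not show
about real-data studies.

## Transport model

The forward model maps monthly gridded emissions and edge boundary inflow to
monthly surface concentrations per PM2.5 pathway on a regular coarse lat-lon
grid (default 30×40 cells of 0.8°×1.0°, standing in for a 0.25°×0.3125°
regional domain). Each month is an **independent steady state** of the
conservative flux-form balance

    0 = −∇·(u c) + ∇·(K ∇c) − k c + q + b,

discretised with first-order upwind advection (face velocity = mean of the
two adjacent cells, donor-cell fluxes), a 5-point diffusion stencil with
no-flux edges, first-order deposition k (per-tracer, 0.16–0.45 day⁻¹,
i.e. aerosol lifetimes of a few days), an emission source q (kg month⁻¹
converted to µg m⁻³ s⁻¹ through the cell area × a 1000 m mixing height and
the month length), and advective inflow b of a fixed edge concentration on
inflowing boundary faces. Months are solved independently — there is no
inter-month memory; pollution inherited from previous months is explicitly
out of the model's scope and ends up in the attribution residual.

The discrete operator is assembled as an explicit sparse matrix and the
steady state is obtained by a direct sparse LU solve of `(kI − T) c = q + b`.
This is the same fixed point a CFL-stable explicit iteration would converge
to, but the matrix form makes the adjoint *exactly* the transpose, which is
the property the verification suite leans on. The `substeps` parameter
retains the CFL guard: a configuration whose explicit substep would violate
CFL is rejected with instructions to raise `substeps`.

Transported tracers are sulfate (from SO2 with a 0.60 mass yield applied at
the source), a nitrate potential (from NOx, yield 0.40), gaseous ammonia
(NH3), primary OC and BC, SOA (from the lumped precursor SOAP, yield 0.18),
and fine dust, which has no interior source and enters only through the
boundary — its attribution deliberately lands in the extra-regional/natural
residual. PM2.5 is the sum of seven components: sulfate, nitrate, ammonium
(= 0.35 × ammonia), OC, BC, SOA, dust.

**Nonlinear chemistry.** The single nonlinearity is ammonia-limited nitrate:

    nitrate = smin( potential, 1.8 · softplus(NH3 − 0.354 · sulfate) ),

where 0.354 is the NH3 mass consumed per sulfate mass (2 mol NH3 per mol
SO4²⁻), `softplus`/`smin` are the log-sum-exp smooth max/min with sharpness
τ = 0.5 µg m⁻³ so the model stays differentiable, and the result is clamped
at zero (the smooth min dips slightly negative when both arguments vanish;
the clamp region gets zero derivative in the adjoint). With the flag off the
nitrate equals its potential and the chemistry is exactly linear.

## Exposure fusion

Modelled coarse monthly PM2.5 is corrected toward the synthetic satellite
annual field: per coarse cell, every month is multiplied by the ratio of the
coarse-aggregated satellite annual mean to the model annual mean, clamped to
[0.25, 4] (a bounded multiplicative bias correction; an additive mode was
considered and rejected because a multiplicative correction preserves
nonnegativity and the relative spatial pattern). Cells with a zero model
annual mean receive the satellite annual value directly. The corrected
coarse field is then downscaled to the fine grid (default 120×160, 4×
refinement) using the satellite annual field as the within-parent pattern;
the per-parent area-weighted mean is conserved exactly, with a uniform
fallback where the pattern vanishes.

**Frozen ratios.** All perturbed evaluations — finite-difference gradient
checks, the boundary-perturbation experiment, alternative inventories —
reuse the BASE run's correction ratios and downscaling weights. Re-deriving
the rescaling under a perturbation would largely cancel the very signal
being measured; freezing it also makes the exposure chain a fixed linear map
for the adjoint.

## Health impact and the cost function

Attributable deaths per fine cell and cause follow the population
attributable fraction form given in the README. Relative-risk curves are
tabulated at exposure knots and interpolated piecewise-linearly, with RR = 1
at and below the TMREL (default 2.4 µg m⁻³) and flat extrapolation above the
last knot; low/mid/high curve bounds, country×cause baseline mortality
bounds, and population scaling bounds (−20% / +54%) are carried through to
an all-low / all-high uncertainty bracket on J (no covariance model). There
is no age stratification: one aggregate curve per cause.

**Linear response mode.** The PAF is not homogeneous in exposure, so the
exact first-order identities (contributions summing to 100% of J; 5× the
BC−20 difference equalling the full boundary removal) cannot hold under it.
The pipeline therefore has a *linear mode* — linear chemistry plus a
linearised response `deaths = P · y0/10⁵ · s_d · C` with `s_d` the secant
PAF slope at a reference exposure (default 25 µg m⁻³) — in which J is an
exactly linear functional of (emissions, boundary). The exactness criteria
are stated and tested in that mode; reporting uses the full PAF response,
where the identities hold only to first order and the gap appears as the
residual.

## Adjoint

The cost gradient seeds the reverse sweep: ∂J/∂C per fine cell (analytic,
through the piecewise-linear RR), multiplied by the frozen downscaling
weights and summed over children, times the frozen rescale ratio, gives
∂J/∂C on the coarse annual mean; division by 12 chains through the annual
mean to every month; the pointwise chemistry Jacobian (exact partials of the
smooth min, evaluated at the stored base tracers — one linearisation point
per month, no tape needed) distributes the seed over tracers; and one
transposed LU solve per (month, tracer) lands in emission space. Units are
fixed at deaths·kg⁻¹ so contribution arithmetic needs no hidden conversions.
Sensitivities are disaggregated to the fine grid by replication (they are
intensive in emitted mass).

**Verification.** Three layers, all in the test suite and the acceptance
script: (i) operator transpose identities ⟨Au, w⟩ = ⟨u, Aᵀw⟩ to 1e-10 for
the transport matrix and the full steady-state solve, all months; (ii)
central finite differences of J at ±0.5% emission perturbations — the
perturbed J is differenced cell-wise before summation, because subtracting
two ~10⁵-death totals loses ~ε·J of signal to cancellation; samples are
drawn with probability proportional to emitted mass, since the
finite-difference signal of a near-massless entry (λ·δE ≪ ε·J) is not
resolvable in double precision no matter how exact the adjoint is; (iii)
global identities: Σ λ_E ⊙ E = J to machine precision in linear mode with
zero boundary, and 5×(J_BASE − J_BC−20) equal to the full boundary removal.

**First-order validity range.** In the full nonlinear configuration, uniform
emission scalings of ±35% keep the first-order predicted ΔJ within 10% of
the brute-force ΔJ (measured ≈ 8% at the extremes, dominated by the
concavity of the PAF response; the chemistry nonlinearity contributes < 1%).
This range is a design target of the toy: the synthetic RR curves use a
log-shaped form `RR = 1 + a·log1p((C − TMREL)/b)` with half-saturation b of
30–40 µg m⁻³, i.e. quasi-linear at the 10–30 µg m⁻³ exposures the world
produces, which is also where GBD-style curves are flattest.

## Synthetic world

The generator is the study's data source, not a fixture: everything the
pipeline consumes comes from one seeded configuration, with named RNG
substreams per component so regenerating with one field changed (say,
emission totals) leaves unrelated components (the country mask, population)
bit-identical.

* **Domain**: an ocean band west of −10°E (exercising unassigned cells and
  shipping corridors), land tiled by 12 contiguous country blocks, all
  receptor-flagged by default.
* **Population**: 598.97 million total; log-normal urban clusters (25
  Gaussian cities, log-normal amplitudes) on a uniform rural floor.
* **Emissions**: 2015 totals per (species, main sector) at European
  magnitudes (e.g. NOx 7.9×10⁹ kg yr⁻¹, NH3 4.0×10⁹), split to the 16
  detailed sectors by fixed fractions and laid out by archetype — point
  sources (energy, industry), population-proportional area sources
  (residential, waste), corridors between cities (road transport), ocean
  lanes (shipping), cross-domain lines plus city nodes (aviation), cropland
  blocks (agriculture) — each modulated by a seasonal profile (winter
  residential-heating peak, Feb–Apr agricultural-crops/waste-burning peak,
  12 weights summing to 12). The 2005 inventory divides each species by
  (1 + its 2005→2015 relative change): NH3 −1.3%, NOx −19.3%, SO2 −34.9%,
  SOAP −26.8%; OC −5% and BC −15% are package choices (these
  residential-dominated species changed little over the period).
* **Health**: country mortality totals grade west→east from 295 to 1,025
  deaths per 10⁵ across the six causes (±10% country noise), split so IHD
  and stroke dominate; RR bounds at 0.55/1.65 of the mid excess risk,
  mortality bounds at 0.85/1.2.
* **Meteorology**: westerly mean wind 3 m s⁻¹ with a ±1.2 m s⁻¹ seasonal
  cycle and smoothed spatial noise; diffusivity 4×10⁴ m² s⁻¹.
* **Boundary inflow**: fixed edge concentrations per tracer (sulfate 3.0,
  SOA 2.5, dust 6.25 µg m⁻³, …), sized so the boundary-attributable share of
  deaths lands near a quarter — the magnitude regional studies report for
  extra-regional influence.
* **Satellite**: a noise-free truth proxy (background 7 µg m⁻³ plus a
  smoothed population/emission-density signal, square-root-compressed so the
  urban-to-rural contrast stays at the 2–3× of real annual PM2.5 maps,
  scaled to a 12 µg m⁻³ land mean) times multiplicative log-normal noise
  with mean 1 and CV 0.10. The truth proxy is deliberately *not* the toy
  model's own output, mirroring the independence of a hybrid satellite
  product.

With the default seed this yields a population-weighted exposure of
~22 µg m⁻³ and a deaths split of roughly 59% domestic anthropogenic / 22%
extra-regional / 18% residual — the structural fingerprint of a European
attribution study.

**What passing tests do not show.** The generator reproduces statistical
structure, not geography or chemistry: no real terrain or country shapes, no
gas-phase chemistry or aerosol thermodynamics, no vertical structure, no
inter-month transport memory, single-valued boundary concentrations rather
than time-resolved fields, and emission patterns that are archetypes rather
than inventories. Green tests certify the *method* — adjoint exactness,
bookkeeping closure, linearity ranges, determinism — and say nothing about
agreement with any real region's death counts or sector rankings.

## Numerical choices and conventions

* Grids are cell-centred, regular, half-open bounds; fine grids nest in
  coarse by integer factors (checked to 1e-6° on edges). Relative areas are
  cos(latitude) normalised per grid; physical areas use a 6371 km sphere.
* Aggregation of intensive fields is area-weighted; inventories aggregate by
  mass sum. Disaggregation conserves the per-parent area-weighted mean
  exactly; zero-pattern parents fall back to uniform with a warning.
* Steady-state solves: scipy `splu`; one factorisation per (month, tracer),
  cached and reused by perturbed evaluations and the adjoint.
* Percent shares are rounded half-up (decimal arithmetic) to one decimal;
  bound ratios to integers; rankings break ties lexicographically.
* Gridded I/O is CF-style NetCDF3 (xarray, scipy backend) — coordinate
  variables and units attributes are required on read; tables are UTF-8 CSV.
  All pipeline outputs are timestamp-free, so a rerun with the same
  configuration is byte-identical.
* Default problem sizes (30×40 coarse, 120×160 fine, 30-sample gradient
  checks) keep a full pipeline run near ten seconds and the whole
  verification suite under a minute on one CPU.

## Known limitations

* The extra-regional per-cell deaths are death-based (5× the per-cell death
  difference of the BC−20 run); an exposure-based redistribution variant
  would differ where population and exposure changes decouple.
* First-order contributions are not renormalised to J under nonlinearity by
  default (`renormalize_to_J` exists as a switch); the gap is reported as
  the residual rather than spread over sources.
* The all-low/all-high uncertainty bracket ignores covariance between
  population, mortality and RR uncertainty and so overstates the spread
  relative to a joint treatment.
* The linear-response secant slope depends on its reference exposure; 25
  µg m⁻³ sits mid-range of the synthetic exposure distribution, but the
  linear mode is a verification device, not a health model.
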