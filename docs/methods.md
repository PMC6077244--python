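# Methods

## Model

The respiratory tract is a rigid one-dimensional trumpet: axial coordinate
`z` from the mouth (`z = 0`) to the distal alveolar end (`z = L`), with all
2^g parallel airways of Weibel generation `g` lumped into one cross-section.
Gas transport combines advection at the (single, axially constant)
volumetric breathing flow, gas-phase axial diffusion through the airway
cross-section, and radial exchange with tissue/blood.  Radial exchange is
linear in the local concentration: each compartment (airway tissue, alveolar
capillary blood) is characterized by a maximum volumetric flux `J` (pl/s,
the flux into CO-free gas) and a diffusing capacity `D` (pl s⁻¹ ppb⁻¹), so
the net local source vanishes at the equilibrium concentration `J/D`.  The
model is species-agnostic; CO and NO differ only in their parameter values
and gas-phase diffusivities (0.21 and 0.23 cm²/s).

Working units are chosen so no conversion constants appear in the transport
equation: concentrations in ppb (mole fraction), flows in ml/s, fluxes in
pl/s.  Since 1 pl = 10⁻⁹ cm³, a flux of 1 pl/s equals 1 ppb·cm³/s exactly.

### Geometry

* Conducting airways (`0 ≤ z ≤ L − z1`): power-law cross-section
  `A_aw = A_c1((L−z)/z1)^(−m)` with `m = 2`, `A_c1 = 217 cm²`, giving a
  closed-form dead-space volume `A_c1 z1 (1 − z1/L) ≈ 127 ml`.
* Alveolar region (last `z1 = 0.6 cm`): airway duct areas from a bundled
  per-generation table (editable CSV), linearly interpolated; the seven
  alveolated generations are placed at equal spacing across the region.
  The bundled duct areas and alveoli fractions approximate the rescaled
  Weibel distribution (areas scaled so generation 17 matches `A_c1`; the
  alveoli fractions increase geometrically to a peak fraction
  `N_max/N_t = 0.549` at generation 23).  Exact rescaled values are not
  published as a table; users with better morphometry can replace the CSV.
* Alveolar compartment: the storage term applies the total alveolar
  cross-section per unit axial distance, `A_alv(z) = (N_alv(z)/N_t)·A_cA`,
  so the alveolar gas capacity integrates to `A_cA` millilitres (39.4 l for
  the default constants).  This per-length reading of the storage term is
  what gives the alveolar reservoir its several-second fill time constant
  `A_cA/D_A` (≈ 5 s for healthy CO parameters); it is the only reading we
  found consistent with the reference end-tidal values across maneuvers
  (end-tidal/equilibrium ratios follow `1 − exp(−T_breath·D_A/A_cA)` to a
  few percent).  The alternative — rescaling the alveolar area so the whole
  trumpet holds 3,700 ml — makes the alveolar reservoir equilibrate within
  ~0.5 s and forces end-tidal CO onto the alveolar equilibrium, contrary to
  the reference behaviour.  `V_total = 3700 ml` is kept as metadata of the
  airway rescale.
* `N_max` is computed as the grid maximum of the alveolar density (per cm),
  making `N_alv/N_max` dimensionless by construction; the literature count
  (263.3e6) is retained as metadata only, since a per-length reading of it
  is inconsistent with the total count over 0.6 cm.
* Source weights: `w_alv = N_alv/N_t` (integrates to 1 exactly);
  `w_aw ∝ A_aw(1 − N_alv/N_max)`, normalized to integrate to 1.  With both
  weights normalized, the configured `J`/`D` totals are conserved regardless
  of grid resolution.

### Numerics

Method of lines on a uniform grid (default `dz = 0.1 cm`, 273 nodes):
first-order upwind advection selected by the flow sign, conservative central
differencing of the diffusion term with arithmetic-mean face areas (airway
area only, as the trumpet's alveoli do not conduct axially), and backward
Euler in time (default `dt = 0.01 s`) with the linear sink terms in the
implicit matrix.  Each step solves one tridiagonal system (LAPACK banded
solve; within a constant-flow phase the matrix is LU-factorized once and
reused).  The scheme is an M-matrix system: unconditionally stable and
positivity-preserving; concentrations more negative than −10⁻⁹ ppb abort
with a solver error, smaller round-off negatives are clipped.

Boundary conditions: during inhalation the mouth node is held at the inhaled
ambient concentration (Dirichlet row); during breath-hold and exhalation the
mouth is zero-gradient; the distal end is zero-gradient always.
Zero-gradient ends are realized by ghost-node reflection, which keeps the
full storage/source physics at the boundary node and makes the boundary
diffusive flux exactly zero.  A literal constraint row (`C_0 = C_1`) would
silently discard the distal node's source — that node carries the largest
alveolar weight — so the reflection form is used instead.

Verification: a 10-node instance agrees with an independently assembled
explicit integration (dt = 10⁻⁵ s) to < 0.5%; with sources and flow off,
total CO content is conserved to < 10⁻⁶ over 1,000 steps; halving `dz` or
`dt` moves the simulated end-tidal value by < 1% / < 0.5%.

### Maneuvers

A breathing cycle is inhalation at constant `IFR` for `V_in/IFR` seconds,
an optional breath-hold, and exhalation at constant `EFR` for `V_ex/EFR`
seconds; the mouth-node concentration recorded at every exhalation step is
the expirogram.  The default initial state is a CO-free tract and a single
cycle; a preconditioning option repeats cycles until the end-tidal value
changes < 0.5%, for users who prefer a cyclic steady state (for healthy CO
parameters the two differ by a few percent because the alveolar reservoir
does not fully fill in one breath).  Measured flow traces are supported
(piecewise-linear interpolation onto solver steps, phases from the flow
sign); they bypass the per-phase factorization and assemble each step.

## Parameter estimation and fitting

Initial estimates (healthy population): membrane diffusing capacity
`D = A_M K_CO/dx`, converted from cm³ min⁻¹ atm⁻¹ to pl s⁻¹ ppb⁻¹ by the
factor 1/60 (1 cm³ = 10⁹ pl, 1 atm = 10⁹ ppb, 1 min = 60 s); capillary CO
partial pressure from the Haldane relation, converted mmHg → ppb by
10⁹/760; maximum fluxes `J = D·mcapP_CO`, with the airway flux reduced by
the airway-proximal blood-volume fraction (default 0.1, exposed as a
parameter).  These constants are unit-tested against an independent
step-by-step conversion.

Fitting refines the exchange parameters against a measured expirogram:

* Stage 1 (airway): RMS misfit over the first 0.2 s of a breath-hold
  exhalation, varying `J_aw` (optionally `D_aw`), bounds 0–5,000 pl/s and
  0.1–20 pl s⁻¹ ppb⁻¹.  Without a breath-hold the stage refuses to run: the
  early window is then insensitive to the airway parameters.
* Stage 2 (alveolar): RMS misfit over the final third of exhaled volume
  (level and slope of phase III), varying `J_A` and `D_A` within ±50% of
  the start.
* The model-level two-stage fit runs a provisional alveolar fit before the
  airway stage: breath-hold enrichment of the early window is dominated by
  alveolar CO diffusing mouthward, so an alveolar baseline far from the data
  would otherwise push `J_aw` to a bound.
* A joint mode fits any subset of the four parameters across several
  maneuvers simultaneously and reports a normalized sensitivity condition
  number; fits of airway parameters without breath-hold data are flagged.

Searches use bounded trust-region least squares on start-normalized
parameters (2-point finite differences, `diff_step = 10⁻³`), with optional
seeded multi-start.  Typical fits converge in ~10–30 simulator evaluations.

Identifiability, measured on synthetic data at the sensor's 2 ppb noise and
0.14 s sampling: `J_A` and `D_A` are recovered to ≪ 1% from a joint fit
over three exhalation flow rates; `J_aw` from the 0.2 s breath-hold window
has a standard error of ~100 pl/s (the window holds two samples and its
sensitivity is ~0.013 ppb per pl/s), i.e. a median recovery error of ~30%
at a true value of 240 pl/s.  A three-fold airway-flux increase is
nevertheless clearly distinguishable (> 6 ppb shift, three times the noise
floor).  Single-trace airway estimates should therefore be read as
order-of-magnitude; averaging over maneuvers or longer windows is advised.

## Analysis conventions

* End-tidal concentration: mean over the final 5% of exhaled volume
  (window configurable and recorded in summaries).
* Elimination rate: end-tidal × EFR; numerically in pl/s without conversion.
* Phase boundaries: phase I ends at the anatomic dead-space volume from the
  geometry (closed form, ≈127 ml); phase II ends where the profile reaches
  95% of the plateau trend line (least squares over the final third of
  volume), whose slope is the reported phase III slope.  Boundaries are
  descriptive outputs; the fitting stages do not depend on them.

## Synthetic sensor data

The generator simulates a clean expirogram, resamples it at the sensor
acquisition interval (0.14 s) and adds i.i.d. Gaussian noise (SD 2 ppb),
optionally with flow jitter and half-cosine start/end ramps on the recorded
flow channel.  It reproduces the sampling and precision of a real-time
laser-absorption CO sensor, and the near-constant exhalation flow enforced
by a controlled breath sampler.  It does not emulate inter-subject
anatomical variability, intra-breath flow excursions feeding back on the
concentration, instrument drift, or ambient fluctuations — parameter
recovery on these traces therefore validates the estimators, not the
model's adequacy for real lungs.

## Problem sizes

Default study sizes keep a full verification run light: 273-node grid,
0.01 s steps (~10³–10⁴ steps per maneuver, tens of milliseconds each), a
17-point flow sweep, and 20-seed recovery studies; these are the sizes the
test suite and the reproduction script use.

## Known limitations

* The geometry is symmetric and rigid; dead space and oral cavity volumes
  are not separately represented, and cross-sections do not change during
  the breath.
* The alveolar-region duct areas and alveolar distribution are approximate
  defaults; phase II shape is the most sensitive to them.
* A single axial flow ignores regional ventilation inhomogeneity and radial
  velocity profiles.
* No tissue-layer dynamics: `J` and `D` are constant within a breath, so
  slow COHb kinetics and the standard single-breath diffusing-capacity
  (D_LCO) protocol are out of scope.
* End-tidal CO₂ is carried as pass-through metadata only.
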