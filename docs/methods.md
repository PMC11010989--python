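# Methods

`sonodish` simulates the heating of cultured breast-cancer cells in a
Petri dish under pulsed high-intensity focused ultrasound (HIFU), for two
culture configurations: a 2D monolayer (15 µm of cells on a glass
coverslip under DMEM) and 3D spheroids (a homogenised 117 µm cell layer
in hydrogel/RPMI).  The pipeline has two coupled stages: a nonlinear
acoustic solve that yields the steady heat-deposition field, and a
reduced Pennes bioheat solve that integrates the temperature over the
sonication protocol.

## Physical model

### Geometry

The computational domain is one quarter of the dish (mirror symmetry at
x = 0 and y = 0), with the beam axis along z and the transducer surface
at z = 0.  The stack along z is: cooling water → growth medium (DMEM or
hydrogel) → cells → glass coverslip → dish bottom.  Materials vary only
along z.  The thin polymer membrane between cooling water and medium is
acoustically transparent and is not modelled; the spheroid compartment
is treated as a homogeneous layer (the µm-scale voids between hydrogel
spheres are far below the acoustic wavelength).  Layer thicknesses other
than the cell layer are configurable with defaults: growth medium 2 mm,
glass 170 µm (a #1.5 coverslip), dish bottom 1 mm, and a water column
sized so the geometric focus lands mid-cell-layer.

Material constants (density ρ, sound speed c₀, specific heat C, thermal
conductivity k, attenuation α_ref at 1 MHz with power-law exponent η,
nonlinearity B/A) ship as a versioned CSV validated against in-code
reference values.  Fluid-like biological media with no published
acoustic constants (DMEM, hydrogel; B/A of the cell layer) take water's
values, the standard approximation for dilute aqueous media.

### Acoustics

The pressure field obeys the Westervelt equation with thermoviscous loss
and quadratic nonlinearity, written in heterogeneous-medium divergence
form:

    div((1/ρ) grad p) − (1/ρc²) ∂²p/∂t²
        + (δ/ρc⁴) ∂³p/∂t³ + (β/ρ²c⁴) ∂²(p²)/∂t² = 0

* The divergence form reduces to ∇²p inside each homogeneous layer and
  produces the impedance-based interface reflection
  R = (Z₂−Z₁)/(Z₂+Z₁), Z = ρc₀ — a plain Laplacian with per-node c
  would mis-reflect at the water/glass and glass/dish interfaces, which
  carry most of the reflected energy in this geometry.
* δ = 2c₀³α/ω² is the sound diffusivity matched to the power-law
  attenuation α(f) = α_ref (f/f_ref)^η at the drive frequency, so a
  plane wave decays as e^(−αz).  β = 1 + B/2A.
* The transducer drives a Dirichlet plane at z = 0: inside the aperture
  r ≤ a, p = p₀√(1+r²/d²)·sin(ωt + (ωd/c₀)(√(1+r²/d²)−1)).  The phase
  advance at larger radius makes all contributions arrive in phase at
  the geometric focus z = d; the sign convention is validated against a
  Rayleigh–Sommerfeld integral oracle (a phased flat aperture, like any
  finite-gain focused source, peaks slightly pre-focally — ~2.5 % for
  the d = 51.4 mm, 33 mm-aperture, 2 MHz transducer, matching the
  measured 51.2 mm).

### Thermal model

Temperature obeys the Pennes bioheat balance
ρC ∂T/∂t = div(k grad T) − w_b C_b (T − T_b) + gate(t)·Q_US + Q_m, with
Q_US = 2αI = α p_amp²/Z from the acoustic stage.  For a Petri dish there
is no blood flow and metabolic heat is negligible against ultrasound
heating, so perfusion and Q_m default to zero (the terms are retained so
the reduction is explicit and testable).  Material properties are
temperature-independent (liquid-phase assumption below 100 °C).

Boundary conditions: 25 °C initial field everywhere; mirror symmetry at
x = y = 0; the z ends clamped at 25 °C (top: pumped cooling water;
bottom: the lab-temperature surround of the dish).  The lateral dish
wall is adiabatic: polystyrene plus ambient air is nearly insulating
compared with the aqueous column, and — decisive for the model's own
outputs — a lateral wall clamped at 25 °C would pin the cell-plane
minimum near 25 °C, which is incompatible with the near-uniform
low-pressure cell-plane ranges the model is meant to produce (e.g. a
(46.53; 46.59) °C range after five minutes).  A fully clamped mode
remains available (`thermal_boundary: dirichlet`).

### Pulsing

The acoustic steady state is solved once for continuous drive: acoustic
ring-up (tens of µs) is four orders of magnitude faster than burst
periods (~1 s), so the duty cycle gates the *heat source* in the thermal
stage rather than the wave solve.  The gate is integrated exactly over
each thermal step (the ON fraction of [t, t+Δt]), so burst periods need
not align with the step; an `averaged` mode replaces the switching with
its duty-cycle mean.  The default burst period is 1 s (the treatment
protocol fixes duty cycle and duration, not the period; end temperatures
depend on the period only through end-phase ripple, and the gated and
averaged modes agree to < 0.1 °C once the period falls below ~10 thermal
steps — a tested property).

## Numerics

### Wave solver

Finite-volume spatial discretisation on a cell-centred lattice,
dx = dy = 0.2λ, dz = 0.1λ (λ in the cooling water), z spacing
non-uniform so every layer interface coincides with a cell face.  A cell
layer thinner than dz becomes a single thin cell (local refinement) —
the reported metric lives in the cell plane, so it must be a resolved
degree of freedom.  Face weights are distance-weighted harmonic means,
keeping fluxes continuous across material interfaces.

Time integration is an implicit θ-weighted (Newmark-type) scheme with
θ = 1/4 and Δt = 0.01/f₀: the Laplacian acts on
θp^{n+1} + (1−2θ)p^n + θp^{n−1} around a central second difference.
A fully backward (backward-Euler) Laplacian was rejected: von Neumann
analysis gives |g|² = 1/(1 + c²Δt²k²), i.e. ~18 % amplitude loss per
period at this resolution, which would destroy every amplitude-based
validation.  The θ-scheme is unconditionally stable and
amplitude-conserving; its axial phase-speed error is (k dz)²/24 ≈ 1.6 %
at dz = 0.1λ, halving the spacing reduces it fourfold (tested).  The
loss term uses a 4-level backward stencil for ∂³p/∂t³ (stable for
loss numbers δ/(c²Δt) < 0.25; the constructor enforces the bound, and
every real medium here sits orders of magnitude below it), and the
nonlinear term a lagged Picard backward difference of p².  The system
matrix is constant and LU-factorised once per run.

Three discrete calibrations are applied, each derived from the exact
harmonic analysis of the stencil (not fitted):

* **δ rescaling** — the backward third-derivative stencil overshoots the
  decay rate by ~5 % at Δt = 0.01/f₀; δ is rescaled so the scheme's
  exact discrete decay rate equals the target α (two fixed-point
  iterations of the dispersion relation).  Measured 1D decay then
  matches e^(−αz) to 0.2 %.
* **Source amplitude** — a Dirichlet source applied on a face half a
  cell away from the first cell centre drives the discrete medium at
  1/cos(k dz/2) ≈ 1.05 times the prescribed amplitude; the source is
  scaled by cos(k dz/2) with k the discrete wavenumber.
* **Boundary delay** — see below.

### Open boundaries

The far (dish-bottom) face is closed by a characteristic delay line: for
an outgoing wave p = f(t − z/c), the ghost cell one spacing outside
equals the boundary cell delayed by dz/(c Δt) steps (≥ 10 here), with
the delay computed from the *numerical* phase speed and the ghost values
linearly interpolated from a per-cell ring buffer.  This closure is
reflectionless at normal incidence — measured 0.04 % standing-wave
ratio, 0.1 % for a narrowband burst — which is the dominant incidence at
the dish bottom.  A conventional quadratic damping sponge
(∂t → ∂t + σ(z)) is available in front of it but off by default: in the
scalar second-order formulation a damping rate approaching ω itself acts
as an impedance mismatch (reflection ~ σ/2ω), so any sponge strong
enough to absorb within 8 cells reflects far more than the delay line it
would be protecting.  The delay-line closure is only stable for
near-normal incidence, so the lateral walls instead carry the sponge
(capped at σ_max = 0.45ω) in front of a pressure-release wall; lateral
arrivals there are weak edge waves.  With the absorber disabled the far
wall is a hard pressure node and standing waves build up — kept as a
regression guard.

Steady state is declared when the cycle-to-cycle change of the per-cell
amplitude envelope (temporal peak over one period) has relative sup-norm
residual below tolerance, and never before the slowest wave has crossed
the domain.  The production default is 10⁻⁸; desk-scale fixtures use
10⁻⁶ (the envelope at that point changes in the sixth digit, far below
every tolerance asserted on it) and the full-frequency 1D column uses
5×10⁻⁴ because the water/glass cavity against the rigid source plane
rings for thousands of cycles.  Intensity and heating follow from the
envelope: I = p_amp²/2Z, Q_US = 2αI = α p_amp²/Z.

### Heat solver

Backward Euler with Δt = 0.01 s on the same lattice (optionally
transverse-coarsened with conservative Q aggregation), harmonic-mean
face conductivities, LU-factorised once.  The solver is unconditionally
stable and handles the stiff thin-cell layers without restriction.  The
maximum principle, an insulated-box energy balance (enthalpy gain equals
the gated ∫Q dV dt to < 1 %), the adiabatic heating-rate limit
(Q/(ρC) to < 1 %), the two-layer Fourier steady state with continuous
k∇T, and the free-space conduction kernel (to < 2 %) are all tested.

## Desk-scale fixtures

A full-scale run (2 MHz, 51.4 mm path: ~10⁷ acoustic cells, >10⁴ steps)
takes hours on one CPU; it is provided as the opt-in driver
`analysis/04_full_scale.py`.  The test and acceptance runs use scaled
scenarios built by `sonodish.fixtures`, designed to preserve the
dimensionless structure that the study's qualitative conclusions rest
on:

* frequency f₀ → 100 kHz (factor s = 0.05); focal distance 4λ with the
  aperture ratio a/d preserved; cell and glass layers keep their
  thickness in wavelengths; domain ≲ 10⁴ cells.
* attenuation evaluated at the full-scale frequency and multiplied by s,
  preserving every medium's attenuation-per-wavelength αλ and hence the
  relative absorbed fractions of the layers;
* duty cycles and pressures unchanged; sonication 3 s, burst period
  0.2 s;
* thermal conductivities multiplied by (λ_full/λ_scaled)²·(SD_full/SD_scaled)
  = 4×10⁴, preserving the conduction Fourier number a_d·SD/λ².  Without
  this, a seconds-long soak is adiabatic while the 5-minute original is
  conduction-dominated — a regime change that inverts the
  monolayer/spheroid comparison.  The DMEM:hydrogel conductivity ratio,
  the mechanism behind that comparison, is untouched.

Scaled runs have O(1) focusing gain (d = 4λ against 68λ at full scale),
so temperature rises are in the mK–µK range; the meaningful scaled
outputs are orderings and ratios (rise ∝ p₀², rise increasing with duty
cycle, high-pressure ranges wider than low-pressure by ~(0.661/0.433)²,
low-pressure cell-plane spread ≪ rise), all of which are asserted in the
acceptance suite.  What scaled runs do *not* carry over: absolute
temperatures, nonlinear harmonic generation (the scaled shock distance
is ~10³ wavelengths, so the runs are linear in practice), and the
many-wavelength water column.

The monolayer-vs-spheroid ordering is instead checked on a
**full-frequency 1D column**: the true 2 MHz stack with real
thicknesses, attenuations, conductivities and a 5-minute duty-cycled
soak, with transverse focusing replaced by a plane wave and the water
column shortened to 10λ so the source–glass cavity rings up in ~10³
cycles.  There the DMEM-backed monolayer ends ~0.3 °C above, and the
hydrogel-backed spheroid ~0.02 °C above, the 25 °C baseline at 0.433 MPa
and 15 % duty cycle — the configuration ordering of the study, produced
by the real mechanism (hydrogel conducts deposited heat away ~4× faster
than DMEM).

## Printed-table arithmetic

The packaged experimental/model comparison table is recomputed under two
error conventions because the printed column is not consistent with a
single one: relative-to-experimental reproduces five of six printed
values to ≤0.1 points, relative-to-numerical reproduces the sixth
(15.0 % ≈ 15.4 % vs 18.3 % under the first convention).  Both are
exposed (`experiment_error_table(relative_to=...)`).  The final-range table
yields the focal-to-surroundings gradients 95.71 − 74.01 = 21.7 °C
(monolayer) and 62.01 − 48.01 = 14.0 °C (spheroid) at 30 % duty cycle
and 0.661 MPa.

## Known limitations

* No cavitation, bubble dynamics, radiation force or streaming — the
  model is purely thermal-acoustic, and over-predicts temperature where
  mechanical effects drain acoustic energy.
* Glass is treated as a fluid-like layer (no shear waves), with the same
  constants the property table prescribes.
* The second-order stencil carries ~1.6 % axial phase-speed error at
  dz = 0.1λ and transverse dispersion ~4× larger at dx = 0.2λ; focal
  amplitudes at desk scale are within 1.5 % of the Rayleigh oracle at
  dx = 0.15λ and within 9 % at 0.2λ.
* The 1D full-frequency column retains the rigid source plane of the
  plane-wave idealisation, so its standing-wave pattern is stronger than
  in the focused geometry.
* Exact cooling-water column height and dish radius of the original
  simulations are not recorded; defaults are geometric inferences and
  configurable.
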