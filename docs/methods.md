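# Methods

## Model

The system is a single coarse-grained polyelectrolyte in explicit solvent,
confined to a periodic quasi-one-dimensional channel and driven by an
applied electric field. All quantities are in reduced Lennard-Jones units:
sigma (length), kBT (energy), m (mass), tau = sigma sqrt(m/kBT) (time),
fields in kBT/(e sigma).

**Particles.** Four mobile species plus fixed walls:

| species | label | charge | role |
|---|---|---|---|
| chain monomer | `M` | −1 | bead-spring polyelectrolyte |
| counterion | `C+` | +1 | neutralizes chain + salt |
| coion | `C−` | −1 | salt |
| solvent | `S` | 0 | explicit WCA fluid |
| wall | `W` | 0 | fixed, uncharged |

All particles are unit-mass WCA spheres: purely repulsive Lennard-Jones,
`U = 4 eps [(sigma/r)^12 − (sigma/r)^6] + eps` cut at `2^(1/6) sigma` and
shifted to zero, with `eps = 1 kBT`. Consecutive monomers are bonded by
FENE springs `U = −(k R0²/2) ln(1 − (r/R0)²)` with `k = 7 kBT/sigma²`,
`R0 = 2.4 sigma`. Charged species interact through a Coulomb potential
`U = kBT lB q_i q_j / r` with Bjerrum length `lB = 1 sigma`, implemented as
a shifted-force truncation at `r_c = 8 sigma` (energy and force both
continuous and zero at the cut). At the working salt concentration
(0.0291 sigma⁻³ of each monovalent species) the Debye length is 1.17 sigma,
so the truncation discards only interactions screened by a factor
~e^(−r_c/λD) ≈ 10⁻³. The electrostatics sits behind a single engine code
path, so a lattice-sum backend could replace it; observables that probe
long-range force correlations (the friction plateau at large control
radius) are the ones that would move if it did.

**Geometry.** The channel is a cylinder of mean radius R0 aligned with z
(the only periodic direction). Undulating members of the family modulate
the wall radius as `r(z) = R0 + A sin(k·2πz/L)` with fundamental
wavelength `L = 57.11 sigma` and amplitude `A = 0.25 R0`; harmonic
multipliers k ∈ {1, 2, 6, 8} correspond to geometry indices 2, 4, 12, 16,
and k = 0 is the smooth cylinder (index 0). With R0 = 6 the wall radius
spans [4.5, 7.5] sigma. Geometry labels combine the field protocol with the
index: `P` for a purely longitudinal field, `T` for longitudinal plus
transverse (the transverse axis is laboratory x; for these rotationally
symmetric channels any fixed perpendicular axis is equivalent).

Walls are a single layer of fixed, uncharged WCA particles placed on the
analytic surface on an approximately triangular lattice with target spacing
1.0 sigma (rows spaced `a·sqrt(3)/2` along the meridian, alternate rows
offset by half an azimuthal spacing). One sigma-spaced layer presents a
WCA barrier of order 10³ kBT through the largest lattice hole, so a single
layer is impermeable and a second shell would be inert. The undulation
phase is `sin` (profile equals R0 at z = 0); any phase is equivalent under
a z-translation.

**Composition.** Counts are referred to the accessible channel volume
`V = ∫ π r(z)² dz` (not the bounding box). Counterions number
`round(c·V)` with `c = 0.0291 sigma⁻³`; coions are reduced by the chain
length N so the mobile charge sums to zero exactly. The alternative
convention (coions at the set concentration, N extra counterions) is
selectable; the two differ by ≲10% in ion count at the smallest boxes.
Solvent numbers `round(0.82·V)` over the same volume — the density is
treated as a set value and local overpacking relaxes during push-off.

## Integration and thermostatting

Velocity-Verlet at `dt = 0.008 tau` wrapped in half-step Nosé–Hoover
updates (single thermostat, no chains), coupling mass
`Q = g kBT τ_NH²` with `τ_NH = 100 dt` and g the thermal degrees of
freedom. Because the field drives steady electroosmotic streaming, the
thermostat is profile-unbiased by default: kinetic energy is measured on
*peculiar* velocities — each mobile species' instantaneous mean velocity is
subtracted first — so the streaming that the drift observables measure is
not damped as heat. One streaming mode (3 degrees of freedom) per species
group is removed from g. A naive lab-frame coupling is available for
comparison; with it, every drift observable is biased low.

Runs follow push-off → field-off equilibration → field-on production.
Push-off relaxes the build-time packing: the WCA force magnitude is capped,
ramped geometrically from 200 to 2000 over (default) 2000 steps, with
speeds clipped at 4 sigma/tau and velocities rescaled to T = 1 every 25
steps. The cap floor is deliberately stiff: the builder guarantees ≥ 0.85
sigma separations, where the WCA force is ~90, so a cap of 200 never
softens genuine contacts — while a soft-start cap (of order 10) would let
hot particles step through the single-layer wall before it ramps up.
Build-time placement itself puts ions and solvent on a jittered cubic
lattice sized to the required count (random sequential insertion jams at
these densities); the lattice melts within the first few hundred push-off
steps.

NVE integration (thermostat off) conserves energy to well below 10⁻⁴
relative drift per step at dt = 0.008 and is the integrator's correctness
oracle. z-coordinates are wrapped into [0, Lz) with per-particle additive
offsets, so unwrapped coordinates are exact.

## Observables

* **Drift velocity** — least-squares slope of the unwrapped species
  center-of-mass z against time over the production window. The regression
  standard error understates the truth for correlated residuals; paired
  comparisons should use matched seeds.
* **Shell-averaged fluid flow** — per frame, each fluid particle is
  assigned once to the radial shell `[r, r+δr)` of its *minimum* distance
  to any chain monomer (deduplicated where per-monomer control spheres
  overlap), and axial velocities are averaged per shell over particles and
  frames, in the laboratory frame. Default `δr = 0.5 sigma`.
* **Electrolyte friction** — the bare Coulomb forces `kBT lB q_i q_j/r²`
  exerted on each monomer by the free ions (counterions and coions only)
  inside a control radius r are recorded in time; the instantaneous
  chain-average force is subtracted; each monomer's residual-force
  autocorrelation (3-vector dot product, FFT-estimated) is integrated over
  lag by the trapezoid rule and divided by kBT; the total friction is the
  monomer average. The estimator uses the bare inverse-square law by
  definition, independent of the engine's truncation. The default lag
  cutoff is 10% of the series duration and the running integral is
  returned, because the correlation has a slow t^(−3/2) hydrodynamic tail
  after its fast exponential decay: a warning is issued when the running
  integral has not plateaued (> 5% relative drift over the last decade of
  lags). Friction-vs-radius curves report a plateau value as the mean over
  the three largest control radii. Force series need denser sampling than
  typical frame strides; production runs can record charged-particle
  positions on a finer probe stride for this purpose.
* **Wall contacts** — a monomer is in contact when its minimum distance to
  any wall particle is below `2^(1/6) sigma` (the WCA cut); the per-frame
  count is time-averaged and normalised by N.
* **Chain extension** — per-frame `|z_max − z_min|` of the chain after a
  minimum-image walk along the bonds makes it whole across the periodic
  boundary, time-averaged and normalised by `b·N`.
* **Density maps** — (x, y) histograms averaged over frames and z, divided
  by bin volume.

Statistical errors on time averages use block averaging with 10 blocks.

## Synthetic fixtures as estimator oracles

Every estimator is validated without MD:

* constant-drift (optionally noisy) trajectories → the drift estimator is
  exact on the noiseless fixture;
* Ornstein–Uhlenbeck force processes generated with the exact discrete
  transition kernel `F(t+dt) = a F(t) + s sqrt(1−a²) ξ`, `a = e^(−dt/τ_c)`,
  stationary start — the friction integral per monomer is analytically
  `3 s² τ_c`, and `3 s² τ_c (1 − 1/N)` after chain-mean subtraction, so the
  estimator's only error is statistical;
* tracers around a straight rod with prescribed axial flow
  `v0 e^(−d/ℓ)` → shell averages are checked against an independent
  Monte-Carlo average of the same field;
* uniform ideal-gas fillings of a channel → density maps and volume
  bookkeeping.

These fixtures emulate the *statistics* the estimators consume, not the
physics that produces them: passing them shows the estimators are correct,
not that the simulated channels reproduce any particular laboratory
system.

## Problem sizes and defaults

Full-scale studies of this kind use boxes of 565–1130 sigma and ~10⁷ steps;
this package's defaults are desk-scale: one undulation wavelength
(Lz = 57.11 sigma), chain length 30, R0 = 4 sigma for the reference runs,
2×10⁵ production steps, frame stride 1000. At that scale the qualitative
transverse-field effects (drift ordering, friction ordering, contact
counts) are resolvable with matched seeds, while quantitative
chain-length sweeps (velocity plateaus versus N, pulsed-field separation
curves) are not — they would need the full-scale runs.

## Effective density and sluggish transport

The solvent count is `round(0.82 V)` over the geometric channel volume, but
fluid centers cannot approach the wall layer closer than roughly one WCA
contact distance. The fluid therefore lives in a smaller volume than it was
counted for, and the *effective* center density exceeds 0.82 by the factor
`R²/(R − d_w)²` with a wall standoff d_w ≈ 0.8–0.9 sigma. At the reference
radius R0 = 6 this gives ≈ 1.1 sigma⁻³ — a deeply supercooled WCA liquid
(measured solvent self-diffusion D ≈ 3×10⁻³ sigma²/tau) — and at the
narrow test radius R0 = 4 it gives ≈ 1.4 sigma⁻³, which is jammed solid
(the mean-square displacement saturates). This is a property of the stated
composition convention, not an implementation artifact, and it explains why
full-scale studies of this system need ~10⁷ steps: drift velocities at
unit field are of order 10⁻³–10⁻⁴ sigma/tau. Consequences adopted here:

* local, vibrational observables (bond length, temperature, geometry) are
  measured in the narrow R0 = 4 channel as prescribed;
* transport comparisons (drift, electroosmotic separation, wall contacts
  under transverse fields) use the reference radius R0 = 6 with a shortened
  box, where the fluid is mobile;
* the electrolyte-friction estimator is insensitive to this distinction
  (it measures Coulomb force fluctuations, which thrive even in the glassy
  matrix).

## Known limitations and deliberate deviations

* **Equilibrium bond length.** With the model constants as printed
  (FENE k = 7, R0 = 2.4, eps = 1, lB = 1, kBT = 1) the mean bond length is
  ~1.05 sigma when bonded neighbours keep their WCA repulsion and
  ~0.57 sigma when they do not (an isolated-bond Boltzmann average gives
  1.12 and 0.72; the dense environment shifts both down). The commonly
  quoted charge spacing b ≈ 0.93 sigma for this parameter set is *not*
  reproduced under either bonded-exclusion convention; the package default
  keeps bonded WCA on and reports extensions normalised by a configurable
  b (default 0.93 for comparability).
* Electrostatics is truncated, not lattice-summed (see above).
* Hydrodynamics is explicit-solvent WCA fluid; no Lennard-Jones attraction,
  no slip-boundary continuum modelling.
* The friction estimator integrates to a finite lag; the t^(−3/2) tail is
  reported (running integral) but not extrapolated by default.
* One chain per box, monovalent ions only, uncharged walls.
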