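# Methods

## Model

`glycodpd` simulates two opposing glycocalyx brushes — wall-tethered
endothelial-glycocalyx (EG) chains and plane-driven red-blood-cell (RBC)
glycocalyx chains — in explicit dissipative-particle-dynamics (DPD) solvent,
and measures how the moving brush deforms the tethered one through the
near-field flow.

All quantities are in reduced DPD units: the cutoff r_c, the thermal energy
k_B T, and the bead mass are 1; τ = r_c √(m / k_B T) is the time unit.

**Pair forces.** Beads interact within r_c through the standard three-term
DPD force: a soft conservative repulsion F^C = a_ij w(r) ê, a dissipative
term F^D = −β w(r)² (ê·v_ij) ê, and a random term
F^R = √(2 β k_B T / Δt) w(r) α ê, with w(r) = 1 − r/r_c and α a unit normal.
The amplitudes are tied by fluctuation–dissipation, so the pair forces act
as a momentum-conserving thermostat. Repulsion maxima by species:
a_ww = 25, a_gw = 26.3, a_gg = 30 (both glycocalyx species count as g);
β = 4.5 everywhere; Δt = 0.001 τ.

**Chains.** A glycocalyx (heparan sulfate) chain is a bead-string of N_b
beads (60 at full scale) joined by harmonic springs E = k_s (r − b0)² with
k_s = 100 k_B T/r_c² and b0 = 0.5 r_c — note the printed potential has no ½
prefactor, so the effective spring constant is 2 k_s — and straightened by a
bending term E = ½ k_E (φ − π)² on consecutive triples. The flexural
rigidity maps through the Euler–Bernoulli relation EI = k_E b0; the baseline
k_E/2 = 231 gives EI ≈ 490 pN·nm at physiological temperature, the measured
stiffness of heparan sulfate.

**Domain.** The full-scale box is 80 × 45 × 40 r_c³ at bead density
3 r_c⁻³ (432,000 beads), periodic in x and z. In y, soft repulsive walls at
y = 0 and y = Ly push beads back with force a_wall (1 − y/r_c) perpendicular
to the plane (a_wall = a_ww), plus velocity reflection as a safety net; the
wall exerts no tangential force. EG chains stand on the y = 0 wall in a
single row along x at mid-z, anchor spacing d1; their anchor bead is
tethered (never moves). RBC chains hang from the plane y = d0 with the
baseline spacing; their top bead is driven kinematically at a prescribed
x-velocity during production (x advances, y and z held). RBC rows keep the
baseline spacing when the EG spacing is varied, since a case-C spacing of
10 r_c with twelve RBC chains would not fit the box.

**Integrator.** Groot–Warren modified velocity-Verlet with λ = 0.65 and one
force evaluation per step (dissipative forces at λ-predicted velocities).
Bonded pairs also feel the non-bonded pair forces (no exclusions) by
default; a flag excludes 1–2 pairs for sensitivity runs.

**Randomness.** All pair random forces come from a counter-based generator:
each draw is a hash of (seed, step, i, j), mapped to a standard normal by a
rational approximation of the normal quantile (relative error ~1e-9).
Symmetry α_ij = α_ji holds by construction, trajectories are bit-reproducible
for a given seed on one thread, and a restart needs only the step counter
plus the state (positions, velocities, forces).

## Protocol

Each case is built (chains + solvent filled to density, Maxwell velocities,
zero net momentum), equilibrated undriven (200 τ at full scale; drives and
body forces off), then run in production with the drive on. Timed events
fire during production: releasing a tethered chain (displaced upward, tether
removed — the shedding case) or pulsing a velocity on chain tips for a few τ
(the activation case). Initial chain beads get a ±0.05 r_c seeded jitter
(anchors exact) because opposing straight chains on the same lattice line
would produce exactly coincident beads, and chains longer than the gap fold
into a "J" along the wall at build time.

## Scaled-down tiers

The printed cases (432,000 beads, 1.6 × 10⁶ steps each) are cluster-scale.
The package therefore ships two scaled tiers built by the same generator:

- **mini** — 20 × 20 × 10 r_c³, 4 EG + 4 RBC chains × 20 beads,
  20 τ + 60 τ (~12,000 beads);
- **micro** — 10 × 8.5 × 5 r_c³, 4 EG + 4 RBC chains × 12 beads,
  6 τ + 24 τ (~1,275 beads), the tier the test battery and the acceptance
  script run. One micro case takes ~20 s on one CPU.

Scaling preserves the ratios that carry the trend physics rather than the
raw parameters:

- *elastic similarity*: k_E is multiplied by (N_b − 1)/59 so the
  persistence-to-contour ratio — hence the tip-fluctuation amplitude
  relative to the anchor spacing, which drives the density trends — matches
  the full-scale brushes; the short-chain variant keeps the tier's material
  constant (same k_E, half the length), as printed;
- *geometric similarity*: d0/l0 = 32.5/29.5 as printed (the arrays
  interdigitate deeply), the close-separation case scales d0 by 27.5/32.5,
  and flow bins are one anchor spacing wide (which reproduces the canonical
  16 × 9 × 1 grid of 5 × 5 × 40 r_c meshes exactly at full scale);
- *drive similarity*: tier drives are the printed speeds × 3 so the anchor
  displacement per contour length over the shortened production span
  approaches the full-scale ~2.7 l0 (the regime where chains stream behind
  their anchors rather than standing as static rods); the printed
  1 : 10 : 40 speed ratios are preserved. Deflection comparisons are made
  at the plateau (mean over the last half of production), matching the
  comparison of new equilibrated positions rather than the startup
  transient.

What the micro tier does **not** reproduce: absolute observable values
(deformation RMSD, lift force, dispersions are reported in the tier's own
units and sizes), wall-distant bulk flow (the box is a few r_c tall), and
self-averaging — single-case numbers are noisy and all comparative
statements are made on means over three seeds. Passing ordering tests shows
the implemented mechanics reproduce the direction of each reported trend at
reduced scale, not the printed magnitudes.

## Analyses

- **Deflection**: tip-bead x-displacement against the end-of-equilibration
  reference, minimum-imaged in x; relative deflection divides by the contour
  length l0 and averages over chains (central chains only for fast drives,
  where periodic wrap-around matters most).
- **Deformation RMSD**: between consecutive stored structures,
  RMSD = (Σ w_i‖x_i − y_i‖² / (N_b Σ w_i))^½ — the printed normalisation,
  which carries an extra 1/N_b against convention; `printed_form=False`
  selects the conventional denominator (orderings are unaffected).
  "Consecutive" means structures 1 τ apart (the canonical output cadence),
  averaged in 100 τ windows at full scale and scaled windows on tiers.
- **Flow field**: per-mesh mean velocities over a trailing window (last
  400 τ at full scale, last half of production on tiers); per-bin
  orientation θ = atan2(v_y, v_x) in the x–y projection; dispersion is the
  circular standard deviation; distributions are compared with the
  two-sample Kolmogorov–Smirnov test (scipy), cross-checked in the tests
  against a brute-force ECDF supremum and an exact lattice-path p-value.
- **Shear**: v_x(y) from the binned field with central-difference rates, or
  per-frame least-squares slopes over beads in a y-region (the near-RBC
  band, y/d0 ∈ [25/32.5, 30/32.5]); stress f = γ ∂v_x/∂y.
- **Viscosity γ**: calibrated by the periodic-Poiseuille method — a fully
  periodic solvent box driven by a counter-flowing body force (+f along x
  in the lower z half, −f in the upper); each half responds with the
  parabola v_x = (ρf/2γ) z(h−z), and γ comes from the least-squares
  amplitude. The readout uses velocity statistics only; at desk scale an
  instantaneous wall-stress readout is dominated by the random-force noise
  (σ ≈ √(2β k_BT/Δt) ≈ 95 per pair), whereas bead velocities average
  cleanly.
- **Lift**: water-on-chain pair forces are accumulated separately in the
  force kernel and streamed with frames; the lift is the time- and
  bead-averaged y-component on the released chain.
- **RBC response**: a_RBC = f_L A / m and angular acceleration
  R f_AN A / J_L for a cylindrical RBC with A = πR²d (kept verbatim from
  the source model although it carries volume dimensions — a construction
  warning is emitted) and J_L = mR²/2. The source's rearrangement
  w = (J_L/R) F is dimensionally inconsistent; it is exposed read-only and
  never feeds results.
- **Units**: r_c = 0.5 nm, τ = 0.05 µs (middle of the stated 0.01–0.1 µs
  range), k_B T = 4.28 pN·nm at 310 K (the temperature behind the pN
  conversions is not stated; 310 K is the physiological choice), giving a
  force unit of 8.56 pN inside the stated 1–10 pN order.

## Numerical choices and degenerate inputs

- Cell-list pair search (cell edge ≥ r_c, rebuilt every step, half stencil,
  cell-sorted gather for locality); boxes under 3 r_c across a periodic
  axis fall back to an O(N²) loop.
- Exactly coincident interacting beads, zero-length bonds, and degenerate
  angle arms raise explicit errors (force direction undefined).
- The bend force factor (φ − π)/sin φ is evaluated with sin φ clamped at
  1e-8; the limit at φ → π is finite.
- Equilibrium fluctuation diagnostics of the bonded potentials use a BAOAB
  Langevin sampler: the pairwise DPD thermostat acts only along bond
  directions and cannot thermalise the transverse motion of an isolated
  molecule. The trimer is sampled in the x–y plane, where the angle measure
  is flat and the width is exactly √(k_B T/k_E); in 3-D the sin φ Jacobian
  would distort it. The dimer is sampled in 3-D (the r² measure shifts its
  width by ~2%, well inside the test band).
- The kinetic temperature statistic averages free beads only
  (Σ m v²/3N_free); tethered and driven beads carry no thermal velocity.

## Known limitations

- Single row of chains along x (z-replication is a straightforward
  extension, not built); no electrostatics, no RBC membrane mechanics, no
  tumbling/tank-treading, no Lees–Edwards shear.
- The two-compartment flow presets ("slow"/"fast" body forces on water) are
  qualitative by design; the plane-channel estimate used to set them ignores
  the brush drag.
- The printed contour (60 beads × 0.5 r_c at r_c = 0.5 nm → 14.75 nm) is
  shorter than the ~30 nm heparan-sulfate length the bead count was chosen
  for; the reduced-unit model is implemented as printed and the physical
  mapping is left to the user.
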