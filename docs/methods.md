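# Methods

## Problem and approach

Long conductive DBS leads couple to the RF electric field of an MRI
transmit coil (the "antenna effect"), concentrating power at the exposed
electrode tip. With parallel transmission (pTx), the per-channel drive
amplitudes A_n and phases phi_n become degrees of freedom: because every
field is linear in the drives,

    E_tot(r)   = sum_n A_n e^{i phi_n} e_n(r)
    B1+_tot(r) = sum_n A_n e^{i phi_n} b1+_n(r),

the drives can be chosen to null the tip field while retaining a usable
transmit field. `ptxshim` implements this as a constrained trade-off:
minimize, by Nelder-Mead simplex over the 2N-1 free real parameters,

    J(A, phi) = s_VOI(|B1+_tot|) / mu_VOI(|B1+_tot|)
              + lambda * mu_ROM(|E_tot|^2 / |E_quad|^2),

the coefficient of variation (COV) of |B1+| over an elliptical-column
volume of interest (VOI) plus a weighted mean of tip-region E-field
power relative to the quadrature reference. SAR is sigma|E|^2/(2 rho)
per voxel; the tip metric is the mass-weighted average over a
whole-voxel cube grown around the exposed tip until it holds 1 g of
tissue (the ROM). Temperature is evaluated with an explicit
finite-difference Pennes bioheat solver.

The procedure per patient and coil configuration:

1. **Precheck.** Normalize quadrature drive (A_n = 1, phi_n = 2 pi n/N)
   to the shim target (mean |B1+| over the VOI = 1 uT) and evaluate the
   ROM 1 g SAR. Below the 0.4 W/kg working limit the quadrature mode is
   accepted and no optimization runs; this also keeps near-zero
   |E_quad|^2 denominators out of the cost.
2. **Lambda sweep.** One simplex optimization per lambda on a 13-point
   grid over [0, 6], each initialized at quadrature with seeded
   restarts. lambda = 0 optimizes homogeneity alone; by the top of the
   grid both cost terms have stopped changing.
3. **Selection.** Discard solutions whose ROM 1 g SAR exceeds 0.4 W/kg;
   among the survivors take the minimum-SAR solution whose COV fits a
   ceiling that starts at 10% and is raised in 5-point steps only when
   no solution qualifies.

Weights are re-normalized to the 1 uT target inside every cost
evaluation, which (a) removes the degenerate descent direction where
uniformly shrinking the amplitudes shrinks the E term without physical
meaning, and (b) makes the cost exactly invariant under global amplitude
scaling. The global phase degeneracy is removed by pinning phi_0 = 0;
amplitudes stay non-negative through an absolute-value reparameterization.

## The synthetic electromagnetic surrogate

No full-wave solver is bundled; per-channel maps come from a quasi-static
surrogate whose one non-negotiable property is strict linearity in the
drives, so superposition is exact by construction.

* **B1+ background.** Biot-Savart integration over each rectangular loop
  element wrapped on the coil cylinder, with b1+ = (Bx - i By)/2 — the
  co-rotating component under the e^{+i omega t} phasor convention, so
  that quadrature drive is the constructive circular-polarization mode.
* **E background.** E = -i omega A from the loop's vector potential,
  scaled by a dimensionless calibration factor, plus a spatially uniform
  axial component with channel pattern (u0/N)(e^{-i alpha_n} + 1/2),
  alpha_n the element azimuth. This mimics the end-ring/axial E_z a
  real volume resonator produces: it survives quadrature combination,
  it varies smoothly (in fact not at all) with patient pose, and its
  common-mode half means that nulling the implant coupling does not
  force the co-rotating B1 mode to zero. Without such a term the
  coupling integral is a cancellation residual of the loop potentials
  and is unphysically sensitive to centimetre-scale repositioning.
* **Implant coupling.** A transfer-function-style model: per channel,
  kappa_n = integral of E_n . t-hat along the lead, weighted by
  exp(-(L-s)/l_a) toward the distal end (l_a = 10 cm). The complex
  kappa_n drives a tip E hot spot gain * kappa_n * exp(-d/delta) along
  the tip tangent (delta = 3 mm), added to that channel's e-map, so tip
  heating is a linear functional of the drives — the same structure the
  optimizer exploits in transfer-function descriptions of implant
  heating.

### Calibration of the surrogate (fixed study conditions)

Three scales are free in the surrogate and were fixed once, against the
levels reported for birdcage head coils at 3 T, before the acceptance
suite was built:

| parameter | value | fixes |
|---|---|---|
| `background_e_scale` | 0.53 | quadrature whole-head SAR ~0.15 W/kg at the 1 uT shim target |
| `axial_potential` u0 | 1.6e-7 T m | axial-to-loop coupling balance (~5:1 per channel) |
| `coupling_gain` | 485 m^-1 | birdcage quadrature cohort median tip 1 g SAR ~1.6 W/kg |

With these, the cohort's spread comes only from seeded lead-trajectory
variability. One cohort configuration may land below the 0.4 W/kg
precheck limit and legitimately safe-skip; that is the method's own
decision path, not an error.

### Synthetic patients

The shared phantom is a homogeneous ellipsoidal head (semi-axes
7 x 8 x 6.5 cm) with sigma = 0.69 S/m, eps_r = 67, rho = 1000 kg/m^3 —
tissue-mimicking values at 128 MHz; density is not reported for the
medium and defaults to the gel-phantom scale. Each patient is a seeded
lead trajectory: a four-turn figure-eight (Gerono lemniscate) bundle at
the skull vertex — each turn offset 3 mm along the outward normal with
an in-turn drift, which guarantees strand clearance above the 1.27 mm
lead diameter by construction — plus a straight penetrating segment
through a lateralized burr hole to a jittered deep target. Total arc
length is solved to a per-seed target inside 40-50 cm. Five patients
are left-lateralized, four right-lateralized. The exposed-electrode
span is the distal 7.5 mm (four 1.5 mm contacts at 0.5 mm pitch);
insulated portions deposit no power and carry insulation thermal
properties where they traverse the grid.

Coil geometries: pTx arrays of N = 4 or 8 abutting rectangular loops
(arc = circumference/N: 19.6 cm and 9.8 cm) on a 25 cm diameter, 15 cm
tall cylinder; the reference excitation is a 16-element array on a
28 cm x 35 cm cylinder driven with fixed quadrature weights, standing in
for a 16-rung low-pass birdcage. It is a reference, never optimized.

### What the surrogate does not emulate

Wavelength effects, dielectric loading and eddy currents in tissue,
conductor interactions (tuning/matching/decoupling), heterogeneous
anatomy, and the reshaping of E inside a lossy head. Consequently the
*absolute* pTx-optimized SAR levels and all temperature rises are not
comparable to full-wave values — the exposure model (steady SAR for a
configurable 360 s, standing in for an unspecified refocusing-pulse
sequence) adds a second unconstrained scale. Passing tests demonstrate
that the method's decision logic, its metrics, and its qualitative
cohort behaviour (strong per-patient tip-SAR suppression, the
homogeneity cost, the channel-count advantage, graceful degradation
under generic weights and rigid shifts) are implemented correctly; they
do not validate dosimetry for real patients.

## Numerical choices

* Internal units are SI throughout; voxel membership is by voxel-centre
  test with 0-based indices and world coordinates at voxel centres; the
  coil-assembly centre is the world origin.
* The 1 g ROM uses whole-voxel cube shells (no fractional-voxel or
  surface-interpolation logic): the region stops growing at the first
  shell whose enclosed tissue mass reaches 1 g, making it exactly
  reproducible by a brute-force oracle.
* Default grid spacing 0.39 x 0.45 x 0.35 cm (the field-map resolution);
  the default study grid is 48 x 56 x 48 voxels, chosen so the head
  plus the rigid-shift range stays inside the lattice while a full
  cohort with both robustness arms runs in minutes on one CPU.
* Hampel conditioning of field magnitudes applies the 1-D filter
  (window 5, k = 3, scaled-MAD, truncated edge windows) along each grid
  axis in sequence. A zero MAD degenerates to "replace anything that
  differs from the median". The filter is idempotent on its intended
  input class (smooth data with isolated spikes), not on dense noise.
* The Eq.-ratio denominator |E_quad|^2 is floored at machine epsilon
  times its ROM maximum; sub-floor voxels are excluded from the ROM
  mean.
* Nelder-Mead runs per start at most 400 iterations (fatol 1e-10,
  xatol 1e-6) with 3 seeded restarts; the returned cost never exceeds
  the quadrature starting cost. The iteration cap trades a few percent
  of final-cost polish for a several-fold speedup; the lambda-selection
  outcome is insensitive to it.
* The bioheat solver is forward-Euler with a 7-point Laplacian,
  arithmetic-mean face conductivities, and a Robin surface exchange
  (default 10 W/(m^2 K) against 20 degC ambient; the exchange law is a
  modelling choice — only the ambient temperature is prescribed). The
  time step is half the explicit stability bound; with k -> 0 the bound
  is infinite and a configured cap (60 s) applies. The perfusion term
  is V_b rho_t C_b (T_b - T): combining the printed per-kg-tissue
  perfusion rate with the *tissue* density is the only reading that
  yields a volumetric power density, and the printed thermal
  conductivity unit "J/(m K)" is read as W/(m K).
* Rigid-body displacement draws per-axis rotations uniform in
  [-10 deg, +10 deg] and translations uniform in [-4, +4] cm ("maximum
  range" read as the +- extreme); draws that would push the head
  outside the grid are resampled with bounded retries.
* Group-generic weights average amplitudes arithmetically and phases
  circularly (argument of the mean unit phasor); arithmetic phase
  averaging is available behind a flag but is ill-defined at the 0/2 pi
  wrap. Quartiles use linear interpolation (type 7); outliers are
  points beyond 1.5 IQR. The Wilcoxon signed-rank test discards zero
  differences, midranks ties, and computes the exact two-sided p by
  enumerating all 2^n sign assignments for n <= 15 (tie-corrected
  normal approximation above).
* COV uses the population standard deviation: the VOI is the entire
  population of interest, and the convention is frozen for tests.

## Known limitations

* The antiphase-null regime has a genuine degeneracy: channels with
  *identical* e-maps are nulled by the quadrature reference itself
  (sum of e^{2 pi i n/N} = 0), leaving the ratio term 0/0; the precheck
  would skip such maps. Optimizer analytics therefore use proportional
  (not identical) e-maps, where the null surface exists and the
  reference is finite.
* Whole-head SAR of optimized solutions can fall below the reference in
  this surrogate (real coils deposit more background power when the
  drives depart from quadrature); the whole-head metric is reported but
  no directional claim is made for it.
* The bioheat exposure duration, duty cycle and pulse amplitude of the
  modelled sequence are configuration, not physics; temperature results
  should be compared only across excitations within one run.
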