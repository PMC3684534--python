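# Methods

## Model

The body is a planar serial chain rotating about the vertical axis. The
trunk rotates by θ₃ about a space-fixed axis at the body midline; the
shoulder joint sits on the trunk at a signed lateral offset *s* along the
shoulder line; the upper arm (length L₁, mass m₁, centre of mass at r₁ from
the shoulder, inertia I₁) and the forearm+hand treated as one rigid link
(L₂, m₂, r₂, I₂) complete the chain. Angles are counter-clockwise-positive;
shoulder and elbow are zero with the arm extended along the shoulder line.
Movement is horizontal, so gravity produces no joint torque; tendon/muscle
viscosity and elasticity are not modelled; control is strictly feedforward —
commands are computed before movement onset and never corrected online.

Writing the kinetic energy of the chain and applying the Euler–Lagrange
equations gives τ = H(θ)·θ̈ + A(θ, θ̇) with a symmetric positive-definite
inertia matrix H depending only on θ₁, θ₂ (θ₃ is cyclic) and a
velocity-product vector A. With a₁ = I₁ + m₁r₁² + m₂L₁², a₂ = I₂ + m₂r₂²,
k = L₁m₂r₂, b₁ = (m₁r₁ + m₂L₁)s, b₂ = m₂r₂s, the closed forms are listed in
`trunkreach/dynamics.py`. Each per-joint torque is decomposed by term
structure: *normal inertial* = the diagonal acceleration term, *inertial
interaction* = off-diagonal acceleration terms, *centripetal* = single-θ̇²
terms, *Coriolis* = 2θ̇ᵢθ̇ⱼ cross terms. The components sum to the net torque
identically.

Because the closed forms were derived by hand (symbolically) and hard-coded,
the package carries an independent numerical oracle: the kinetic energy is
evaluated purely from centre-of-mass geometry (complex-step Jacobians), the
inertia matrix recovered by polarisation of that quadratic form, and the
configuration gradients taken by fourth-order finite differences. The test
suite and the `validate` command require closed-form/oracle agreement below
1e-7 N·m on 1000 random states (observed ≈ 3e-8), plus an integrated power
balance d(KE)/dt = Σ τⱼθ̇ⱼ to a relative 1e-6 (observed ≈ 1e-8).

## The misperception experiment

1. **Plan.** The hand follows a straight minimum-jerk quintic between the
   task's printed endpoints, (−0.228, 0.25) m to (−0.2258, 0.65) m in the
   shoulder frame, in 0.4 s (0.4 m amplitude). By default the reach is drawn
   in the **trunk frame**: the planned shoulder/elbow motion relative to the
   trunk is the same with or without rotation, and the trunk rotation enters
   the commands only through the θ₃ kinematic terms of the dynamics. This
   choice follows from three converging observations: the task's planned
   joint angles are those of the no-rotation reach; the plain two-link
   inverse kinematics used for planning contains no rotation term; and under
   this reading the normal-inertial torque is *exactly* unaffected by the
   rotation. A space-fixed target (`target_frame="space"`), where the plan
   compensates the believed rotation kinematically, is retained as an
   option — note that with the default shoulder offset a space-fixed midline
   target drifts out of reach for clockwise rotations beyond ≈ 25°, so that
   mode is only meaningful for small rotations.
2. **Misperceive.** The accurate trunk kinematics time-series is divided by
   a gain G ∈ [1, 1.5]; the misperception magnitude is quoted as
   100·(1 − peak|θ̈₃|scaled / peak|θ̈₃|), which for pure 1/G scaling is
   100·(1 − 1/G) regardless of profile (G = 1.5 → 33.3%).
3. **Corrupt.** The feedforward commands are the inverse dynamics of the
   plan with every θ̇₃, θ̈₃ replaced by the believed (scaled) values. The
   shoulder/elbow kinematics inside the command computation remain the
   accurate plan's; re-planning under the believed rotation is available
   via `plan_with_believed` for the space-fixed mode.
4. **Execute.** The corrupted net shoulder/elbow torques drive the 2×2 arm
   subsystem while the trunk motion is prescribed at its true value (the
   plant feels the real rotation; the full 3×3 inversion is unnecessary
   because the trunk is externally driven). Integration is fixed-step
   classical RK4 on the 1 ms grid with cubic-spline resampling of the
   torque commands between samples (see *Numerical choices*).
5. **Score.** The reference trajectory is the full pipeline at G = 1 — not
   the analytic plan — so integrator bias cancels from every metric. Final
   hand error is the Euclidean distance between executed and reference hand
   positions at the last sample; RMS net-torque changes compare accurate
   rotation commands with the no-rotation reach; per-component torque
   errors are plain sums over samples of (accurate − corrupted), positive
   when the corrupted command is smaller (a dt-weighted integral is
   available via `mode="integral"`); normalized net errors divide the
   summed net error by the underestimation percentage.

## Parameters

| parameter | default | why |
|---|---|---|
| body height, mass | 1.78 m, 80 kg | the task's stated subject |
| segment constants | Winter/Dempster fractions (see `anthropometry.py`) | standard tables; L₂ is forearm+hand (0.254·height) because the printed targets are unreachable with a forearm-only distal link |
| shoulder offset s | 0.2258 m | read from the task geometry: the straight-ahead target sits at x = −0.2258 m in the shoulder frame |
| trunk inertia | cylinder: ½·(0.497·mass)·(0.085·height)² | enters only the trunk torque, not the arm dynamics; coarse is fine, overridable |
| reach | (−0.228, 0.25) → (−0.2258, 0.65) m, 0.4 s | printed values |
| trunk rotation | 40° in 0.4 s, synchronous, quintic | **not a printed value.** The source figures show the profile without numbers; 40°/0.4 s is a realistic vigorous trunk turn whose resulting torque signatures match the printed RMS torque changes well. All profile-dependent outputs carry this provenance note; the amplitude-sensitivity sweep (20–60°) shows every qualitative conclusion is profile-stable |
| G grid | 1.0–1.5 (0 to 33%) | the stated underestimation range; G < 1 (overestimation) is rejected |
| dt | 1 ms | standard for limb dynamics; halving it changes the final hand error by < 1e-6 % |

A note on the quintic: a 0.4 m minimum-jerk reach in 0.4 s has peak speed
1.875·0.4/0.4 = 1.875 m/s — this is a closed-form property of the
polynomial, so the package reports 1.875 m/s even though the task
description quotes 1.73 m/s; the two are mutually inconsistent and the
polynomial wins.

## Numerical choices

- **Planner derivatives are analytic.** Hand-path velocity/acceleration are
  exact polynomial derivatives; joint velocities/accelerations come through
  the arm Jacobian (θ̇ = J⁻¹ẋ, θ̈ = J⁻¹(ẍ − J̇θ̇)). Plain numerical
  differentiation (second-order central stencils, one-sided at the ends) is
  available as `method="numeric"` and agrees within stencil truncation
  error, but its ≈ 1e-3 rad/s² acceleration noise at 1 ms would dominate
  the inverse→forward round-trip error budget, which the analytic path
  keeps at ≈ 2e-10 rad.
- **Torque interpolation is cubic.** RK4 needs commands at half-steps;
  linear interpolation degrades the integrator to O(dt²). A cubic spline
  preserves the round-trip at 1e-6 rad tolerance; `interp="linear"` exists
  for comparison and changes the final error by < 0.1%.
- **Workspace handling.** Planning raises an error naming the first
  unreachable sample; execution only warns if the state grazes the
  workspace boundary (a corrupted command may legitimately deviate the
  arm) and integration continues.
- **Degenerate inputs.** Zero rotation amplitude is allowed (the
  misperception then has nothing to corrupt and the executed path is the
  plain reach for every G); the underestimation percentage of an
  identically-zero profile is defined as 0; normalized net error is
  undefined at 0% and excluded from sweeps.

## What the tests do and do not show

The package is self-validating in the mechanical sense: oracle equivalence,
power balance, positive-definiteness, ID→FD→ID round trips, exact
left/right mirror symmetry, and dt-refinement stability are all asserted at
tight tolerances. These guarantee the simulator solves the stated equations
of motion correctly. They do **not** validate the model against human data:
the trunk-rotation profile is a package default, the anthropometric tables
are population averages, and the feedforward assumption deliberately
excludes the online corrections real subjects make. Qualitative conclusions
(direction asymmetry, monotonic growth of error with misperception,
shoulder-dominant torque cost, Coriolis/centripetal cancellation for CW
rotations at the elbow) are stable across the 20–60° amplitude sweep;
absolute error magnitudes scale with the chosen profile.

One quantitative caveat is documented in the test suite: the summed elbow
inertial-interaction error, −(1−1/G)·∫Ḣ₂₃θ̇₃ dt/dt, is comparable to the
Coriolis+centripetal sum for this reach geometry (the elbow extends ≈ 68°,
so the trunk-coupling inertia varies strongly) and it is direction-odd.
Consequently the CCW/CW ratio of *normalized net* elbow errors falls below
one even though the Coriolis/centripetal cancellation pattern itself is
exactly as described above; the corresponding acceptance test is expected
to fail and is left failing rather than weakened, since every ingredient of
the metric is independently validated.

## Limitations

Planar, three-DOF only; no muscle model, no gravity component in-plane, no
sensory noise, no trial-to-trial adaptation; the trunk is position-driven
(infinite-impedance rotation), so arm-to-trunk reaction torques do not
perturb the rotation; anthropometry is proportional-table based, not
subject-specific.
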