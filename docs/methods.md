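# Model and methods

This note documents the science behind `emdsim`: the model and its
assumptions, the calibration procedure, the numerical scheme, the design
choices that were genuinely open, and the limitations a user should keep in
mind when interpreting results.

## Scope and reduction

The simulator represents an idealized muscle–tendon system: a muscle fiber
bundle of uniform 1 cm² cross-section attached end-to-end to a tendon of the
same cross-section, held isometrically at an applied stretch
λ̄ = l_mts / l_mts0 and stimulated once at the fiber midpoints. Because the
geometry is a uniform-cross-section rod under uniaxial stretch with
isotropic materials, the three-dimensional mechanics reduces to a quasi-1D
series problem: the nominal axial stress is spatially constant, each
cross-section is in the incompressible uniaxial-stress state
(λ₂ = λ₃ = λ⁻¹ᐟ²), and the hydrostatic pressure is eliminated analytically.
The reduction discards transverse heterogeneity, which the idealized
geometry was chosen to exclude in the first place.

The muscle is discretized into 20 equal mechanical elements along the rod so
that the spread of activation during action-potential propagation is
resolved; the passive tendon is a single element. The isolated muscle is the
limit MTR = 1 (no tendon element), not a separate code path.

## Passive mechanics

Both tissues are one-term incompressible Ogden materials,
W = (μ/α)(λ₁^α + λ₂^α + λ₃^α − 3), giving the uniaxial nominal stress
P(λ) = μ(λ^(α−1) − λ^(−α/2−1)). P(1) = 0 and dP/dλ > 0 for α > 1, so every
element response is monotone and the series equilibrium has a unique
solution. Baseline parameters: muscle μ = 2.224 N cm⁻², α = 8.536; tendon
μ = 0.041 N cm⁻², α = 19.06 (the tendon is deliberately more compliant than
the muscle to offset its idealized, unphysiologically large cross-section).
Material variants shorten or lengthen the toe zone of either tissue:
"short toe" is the stiffer pair at λ = 1.2 (tendon 0.097/18.47, muscle
2.798/8.641), "long toe" the more compliant pair (tendon 0.016/19.78,
muscle 1.285/9.182).

The compressive branch (λ < 1) of the Ogden law is used as-is for elements
driven below reference length by activation. This is deliberate: it is what
gives the muscle a finite steady contractile length, and it dominates the
delay at small pre-stretch, where the muscle must compress itself to take up
tendon slack.

## Electrophysiology

The transmembrane potential on each 1-D fiber obeys the monodomain equation
with sealed ends; the ionic model is the two-variable Aliev–Panfilov
membrane in normalized potential (k = 8, a = b = 0.15, ε₀ = 0.002,
μ₁ = 0.2, μ₂ = 0.3 — the standard published set). One global time scale
converts the dimensionless kinetics to milliseconds and is the only
calibrated electrophysiology constant: it is set by a fixed-point iteration
so a midpoint-launched wave on the 1.5 cm reference fiber conducts at
3.5 m/s at C_m = 1 μF cm⁻². The membrane capacitance divides the entire
cable operator (both terms of the monodomain equation carry 1/C_m), so
conduction velocity scales exactly as 1/C_m in the continuum limit:
C_m ∈ {0.58, 1, 1.98} gives ≈ {6.0, 3.5, 1.8} m/s.

Diffusion is solved in material (reference) fiber coordinates; the
deformation dependence of the conduction path is approximated by dilating
each element's activation delay by the pre-stretch muscle stretch when the
drive is applied to the mechanics. This is a documented approximation — the
full deformed-coordinate operator is a second-order effect for the
quasi-static isometric protocols simulated here.

The stimulus is a 90 μA cm⁻² current pulse applied for 2 ms over a 0.15 cm
end-plate region at the fiber midpoint: a point source would be diluted by
diffusion at any grid resolution, and 2 ms is the shortest round duration
that reliably ignites an action potential across all capacitance variants
(a fixed-charge pulse excites a high-capacitance membrane more slowly).

## Excitation–contraction coupling

Calcium release is triggered when the local potential first crosses
v = 0.5 upward and then follows a stereotyped square time course: the gate
opens for 8 ms at rate 1.0 ms⁻¹; free calcium is removed by first-order
reuptake (τ = 30 ms at the baseline rate multiplier). The trigger-based
form was chosen over release proportional to the instantaneous
suprathreshold potential because the phenomenological action potential's
duration stretches with the capacitance-scaled membrane clock; release
gating is a property of the sarcoplasmic-reticulum channels, not of the
membrane capacitance, and the proportional form would turn the
conduction-velocity experiments into excitation–contraction experiments.
(The proportional coupling remains available as
`electrophysiology.calcium_from_potential`.)

Calcium activates the regulatory step of a three-state cross-bridge chain
(off ⇌ D ⇌ A1 ⇌ A2) through a Hill function with coefficient 3 and
half-saturation Ca₅₀ = Ca₅₀⁰ · exp(b(1 − l_hs)); the baseline has
Ca₅₀⁰ = 1 and b = 0 (no length dependence), the length-sensitivity variant
b = 8.3986. Mean distortions x1, x2 of the attached states follow
distribution-moment closure: newly attached bridges carry zero distortion,
the power stroke adds the constant throw x₀ = 8×10⁻³ μm, and both
distortions advect with the half-sarcomere sliding velocity (reference
half-sarcomere length 1.1 μm).

### Rate constants

The individual Razumova-type rates are not observable one by one; they are
pinned by cell-level constraints:

- the saturating-calcium steady state of the chain must reproduce the
  tabulated tetanic post-power-stroke occupancy A2max = 0.044456 that
  normalizes γ (achieved to 0.06%: f = 0.27, f′ = 1.3, h = 0.7, h′ = 0.15,
  g = 0.85 ms⁻¹, k_on = k_off);
- the distortion restoration rates R1 = f′ + h and R2 = h′ + g set the
  unloaded sliding speed ρx₀/[(1+ρ)/R1 + ρ/R2] (ρ = h/(h′+g)); the chosen
  set gives 0.0036 μm/ms, consistent with the tabulated maximum contraction
  velocity of 0.005 cm/ms for the 1.485 cm reference muscle;
- the regulatory on/off rate (k_on = k_off = 0.004 ms⁻¹) and the calcium
  release/reuptake constants set the twitch amplitude and time course; they
  were fixed so that the calibrated twitch reproduces the published
  behavior of this model class: time-to-peak 71 ms at a rate multiplier
  near one, a twitch-to-tetanus ratio near 0.3, and a recruitment
  phenomenology in which recruiting 14.67% of the fibers crosses the 1%
  EMD threshold only after a several-fold longer delay and still-smaller
  fractions sit at the edge of crossing at all.

A single global multiplier scales all chain rates and the reuptake rate
jointly and is calibrated by Brent search so the fixed-length single-AP
twitch peaks at the configured time-to-peak (71 ms baseline, 53/88 ms for
the fast/slow-twitch variants), each to ±0.25 ms.

### Force–length

The force–length relation is the classical piece-wise linear sarcomere
curve, normalized so the plateau spans l_hs ∈ [0.975, 1.07]. The map from
element stretch to half-sarcomere length is l_hs = λ_m / λ_opt with
λ_opt = 1.05, placing the isolated muscle's twitch optimum at the low end
of the 1.05–1.1 window where it is expected.

### Titin

The titin stress θ̄ is a pluggable term that defaults to zero; `run_twitch`
accepts any callable `(ca, λ_m) → θ̄`. The history-dependent sticky-spring
biophysics is out of scope.

## Coupling scheme and numerics

Defaults: fiber grid dx = 0.005 cm; electrophysiology step dt = 0.005 ms
(Heun reaction step + Crank–Nicolson diffusion step, operator splitting);
mechanics/cross-bridge step 0.1 ms with automatic sub-stepping when a rate
multiplier would violate the explicit stability margin; horizon 300 ms.
Measured conduction velocity changes by 0.02% under dx → dx/2, and the EMD
threshold crossing is linearly interpolated between mechanics samples,
bounding its discretization error at about ±0.05 ms. These sizes were
chosen as the coarsest settings whose refinement leaves the reported
quantities unchanged at their printed precision.

Within each mechanics step the cross-bridge reaction/relaxation terms are
advanced explicitly, but the sliding (advection) part of the distortions is
resolved *inside* the series-equilibrium solve: each element's active
stress is treated as affine in its stretch with slope
p_max · f_l · c · (A1 + A2)/(x₀ A2max) — the instantaneous elastic
stiffness of attached cross-bridges. This matters: the cross-bridge
stiffness exceeds the passive stiffness by orders of magnitude at
physiological occupancies, and lagging it explicitly makes the staggered
coupling oscillate and diverge. The equilibrium itself is solved by
safeguarded Newton–bisection on the common nominal stress with warm-started
vectorized Newton inversions per element (the bare Newton iteration
oscillates on the exponential Ogden stiffness).

Because all fibers are identical in the quasi-1D reduction, motor units
sharing a stimulation time share one fiber solution; the monodomain
equation is solved once per configuration and recruitment only shifts the
resulting drive in time. The homogenized activation is the size-weighted
average over recruited units. A twitch run can be truncated once the
recorded stress has risen past the measurement threshold (the model is
causal), which is how the study keeps ~90 experiment runs within a few
minutes on one CPU.

## What the experiments do and do not emulate

All inputs are parameter tables; there is no external data. The experiment
registry reproduces the study conditions exactly: seven stretches 1.05–1.35,
geometry variants (MTR 0.33/0.5/0.66/1, lengths 4.5/27/54 cm), material toe
-zone variants, capacitance (conduction-velocity) variants, calcium length
-sensitivity, twitch-speed variants, and the 225-fiber/10-unit recruitment
protocols (synchronous subsets and progressive recruitment at 0/3/3.5/6.5/10
ms per unit — both published readings of the delay set are runnable). Real
muscle features deliberately absent: aponeurosis, pennation and curved
architectures, viscosity and inertia, fatigue, temperature, repetitive
firing, fiber-type heterogeneity within the pool, and biophysical
ion-channel detail. Passing tests therefore demonstrate the internal
consistency of this idealized system, not quantitative agreement with any
specific animal preparation.

## Known limitations

- **Low-stretch tangency.** With the twitch peak bounded by the recruitment
  phenomenology (γ̄ ≈ 0.3) and the crossing at λ̄ = 1.05 requiring
  γ̄ ≈ 0.22 to overcome the passive compressive stress of the shortening
  muscle, the low-stretch threshold crossing sits near the top of the
  twitch rise. The simulated EMD at 1.05 (~47 ms) is therefore longer than
  the ~32 ms this model family has been reported to produce, and
  differences measured at 1.05 (e.g. the stiff-tendon reduction) are
  correspondingly inflated. A steeper mid-rise — as produced by
  cross-bridge/regulatory cooperativity or an activation-modulated titin
  stress, both outside this reduction — would relieve the tangency.
- **Conduction-time inheritance.** The homogenized activation ramps more
  slowly than the activation spread along the fiber, so EMD differences
  between conduction-velocity variants inherit essentially the full mean
  conduction-time difference (plus the capacitance-dependent end-plate
  charging time): ~3 ms at 4.5 cm and ~10 ms at 27 cm, versus the sub-ms
  and ~4 ms reported for the full 3-D model. The same steep-onset feature
  missing above would shrink this.
- The Aliev–Panfilov action potential has no biophysical ionic basis; only
  its conduction velocity is meaningful.
- Twitch relaxation (after the peak) is not calibrated against anything and
  should not be interpreted.
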