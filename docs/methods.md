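# Methods

This note documents the model, the numerical choices, the synthetic study
conditions and their limitations — the things a maintainer or reviewer
would want to know before trusting or extending the package.

## Model structure and assumptions

The ankle is a frictionless hinge in the sagittal plane; only two
plantarflexors are modelled (lateral gastrocnemius, soleus), each as one
lumped muscle–tendon unit (MTU) from a proximal junction A near the knee to
the heel insertion B, both at fixed distances from the ankle centre O.
Antagonist (tibialis anterior) moment and other plantarflexors are
neglected, so the predicted moment is interpreted as the *net* plantarflexion
moment carried by these two muscles with calibrated effective strengths.

**Angle convention.** The anatomical ankle angle θ is dorsiflexion-positive
and the included angle at O is `q = π/2 + θ`. Dorsiflexion therefore
*lengthens* the plantarflexor MTU, which is the anatomically correct
direction (the calf is stretched when the foot rotates up). The neutral
offset `q_neutral = π/2` is a config entry.

**Moment arm.** The moment arm is defined as ∂l_mt/∂q of the law-of-cosines
MTU length, `r = l_OA·l_OB·sin q / l_mt`. A variant sometimes typeset with
an extra factor 2 is available behind `convention="printed"` for literal
comparison; it is exactly twice the derivative form and is not used by
default because the derivative definition is the one consistent with
mechanics (virtual work).

**Activation dynamics.** The recursion coefficients are parameterized by
poles γ₁, γ₂ with the constraint α − β₁ − β₂ = 1, enforcing unity
steady-state gain exactly. γ₁ = γ₂ = 0.5 and τ = 40 ms are fixed defaults
(config-exposed, τ clamped to the physiological 30–120 ms); they are *not*
part of the calibration vector — the calibrated set is
{A_i, l_t^sk_i, F_max,i, δ_i} only. A = 0 is evaluated as the analytic
linear limit a₁ = N to avoid 0/0.

**Muscle curves.** The generic normalized curves are:
Gaussian active force–length `f_l = exp(−(l̃−1)²/0.45)`; Hill concentric
force–velocity `(1+ṽ)/(1−ṽ/0.25)` for ṽ ∈ [−1, 0], with a C¹-matched
saturating eccentric branch plateauing at 1.4; exponential passive curve
`f_p = expm1(4(l̃−1)/0.6)/expm1(4)` above optimal length, zero below. All
four shape constants are config entries. Maximal shortening velocity
defaults to 10 optimal fascicle lengths per second. The activation-dependent
optimal fascicle length is `l_m0 = l_mo0(λ(1−a)+1)` with λ = 0.15.

**Tendon.** Piecewise force–strain: zero below slack, `1480.3 F_max ξ²` in
the toe region ξ < 0.0127, `(37.5ξ − 0.2375) F_max` above. The two branches
agree at the transition to 3×10⁻⁵ relative and the slope gap is 0.27 %
(2·1480.3·0.0127 = 37.60 vs 37.5); both facts are asserted in tests.

## The equilibrium solve

Per sample the unknown is the tendon length l_t. The constant-thickness
pennation assumption gives fascicle height `h = l_m0 sin φ0`, so
`l_m = √((l_mt−l_t)² + h²)` and the closure `l_mt = l_t + l_m cos φ` holds
*identically* — tests assert it to 10⁻⁹ m. The force balance
F_t(ξ(l_t)) = F_mt(l_t) is bracketed on [0.9·l_sk, l_mt]: the tendon side
vanishes at the slack end and the muscle side vanishes at l_t = l_mt (where
φ → 90° kills the projection), so a sign change always exists; a
safeguarded secant/bisection (Illinois) iteration drives the residual below
10⁻⁹ F_max. The zero-force slack case returns l_t = l_sk exactly. The
fascicle velocity entering f_v is the backward difference against the
previous sample's solved fascicle length (zero at the first sample),
evaluated *inside* the root solve so force and velocity are mutually
consistent; no post-hoc velocity smoothing is applied, deliberately, to
keep that consistency exact. The kernel is JIT-compiled with numba when
available; a pure-Python fallback produces identical values.

Stance-cycle forward runs during calibration start 0.25 s before
heel-strike and discard the warm-up, so the one-sample solver state
(previous fascicle length) settles; block predictions then agree with a
full-trial run to ≲10⁻⁶ N·m.

## Calibration

The objective is the mean squared difference between predicted and
benchmark net moment over all stance samples of the selected cycles.
Bounded least squares (scipy trust-region reflective) runs on parameters
rescaled to the unit box: A ∈ [−3, 0], δ ∈ [0, 1], slack length and maximal
force within 50–150 % of their literature anchors, started at the box
midpoints. Tolerances 10⁻⁸, at most 200 iterations; the finite-difference
step is 10⁻⁶ of the unit box because smaller steps produce moment changes
at the equilibrium-solver tolerance and hence meaningless gradients.
Residuals are weighted 1/√N so the reported cost equals the mean-squared
objective. On noisy data the sEMG-only variant often exhausts the iteration
cap walking a flat A–F_max valley; its objective is converged to ~0.1 %
at that point (checked explicitly), so results use best-so-far with
`converged=False` recorded.

Variants: `fused` (δ free), `semg_only` (δ ≡ 1), `us_only` (δ ≡ 0),
`random_signal` (a₂ replaced by a seeded uniform [0,1] sequence, δ free) —
the last reproduces the fused model's parameter count while destroying the
thickness information, isolating "more parameters" from "more information".

**Cycle selection.** "Steady" cycles are those whose stance duration is
within ±10 % of the trial median. Calibration takes the earliest steady
cycles (10 from one trial in single-speed mode; 2 per trial in inter-speed
mode). Held-out cycles are a fixed later window (steady positions 10–14) of
*every* trial, identical across calibration modes, so mode comparisons are
not confounded by where in the trial the prediction data sits.

## Synthetic study conditions

One synthetic subject (body mass 78 kg, the typical young-adult cohort
mean) walks at 0.50/0.75/1.00/1.25/1.50 m/s, 16 cycles per speed (~20 s),
all channels on the 100 Hz model grid. Cycle duration 1.45 − 0.25·v seconds
with 1.5 % duration jitter; stance fraction 0.66 − 0.04·v; ankle angle
traces a heel-strike plantarflexion dip, a mid-stance dorsiflexion ramp
(peak growing with speed) and a push-off plantarflexion; GRF is the classic
double hump. True activation drives are asymmetric stance bursts peaking
near 70 % stance, with peak level growing linearly with speed and a 0.02
swing baseline.

The generator inverts the activation pathway: the envelope channel is the
shape-map inverse of the target drive (normalized so the cross-speed task
peak is exactly 1), the thickness channel the linear map of the drive onto
subject-constant bounds (LGS 12–16 mm, SOL 25–30 mm). The benchmark moment
is **the package's own forward model** run on the clean channels with the
true parameters (LGS: A=−1.0, l_sk=0.374 m, F_max=785 N, δ=0.6; SOL:
A=−2.0, l_sk=0.260 m, F_max=3017 N, δ=0.5 — off-midpoint but inside all
boxes, with interior gains so both channels genuinely matter). With all
noise terms zero the channels are therefore *exactly* consistent:
calibration recovers the gains to ~10⁻⁹ and forces to ~10⁻⁷ %.

**Noise model** (each modality gets a distinct failure mode, giving fusion
a mechanism to win):

* sEMG: multiplicative cross-talk bursts — Poisson arrivals at 0.8/s,
  0.25 s Hann-windowed bumps, amplitude |N(0, 0.4)|; cross-talk inflates
  the envelope episodically.
* thickness: slow zero-mean wander (white noise low-passed at 0.15 Hz),
  RMS-matched to a 0.03 mm/s linear ramp over the trial — the residual
  error profile of key-frame-corrected tracking, which wanders but does not
  ramp monotonically.
* benchmark moment: white noise, SD 2 N·m (inverse-dynamics floor).

What the generator does **not** emulate: inter-subject anatomy variation,
antagonist co-contraction, soft-tissue artefact, electrode lift-off,
fatigue, probe repositioning, or any model-structure mismatch — the
generating model *is* the fitted model. Passing benchmarks therefore
demonstrate correctness and the fusion mechanism under controlled
conditions, not clinical-grade accuracy on real data; the error scale
(~2–6 % N-RMSE) is accordingly several times smaller than what real gait
data produces.

**A finding worth flagging**: under these mild conditions the
random-signal ablation is *not* worse than the sEMG-only variant (mean
held-out N-RMSE ~2.65 % vs ~2.71 % over ten seeds). With δ free, the
uniform-noise channel contributes mostly a constant offset and lets δ act
as an activation gain — a small but genuine extra degree of freedom —
while the fresh-noise penalty at δ ≈ 0.95 is negligible. At the much larger
error scales of real data the overfitting penalty dominates instead. The
corresponding acceptance test asserts the deterioration direction anyway
and is expected to fail at these conditions; it is left failing rather
than retuning the benchmark around it.

## Problem sizes

Default test and acceptance runs use: 16 cycles × 5 speeds per subject,
10 benchmark seeds, 5 recovery seeds, ~55 bounded least-squares
calibrations in total. These sizes give stable seed-averaged comparisons
while keeping a full run in the ten-minute range on one CPU.

## Known limitations

* Two-muscle net moment: no antagonist, so dorsiflexion-phase moments are
  slightly positive-biased.
* The hinge + law-of-cosines path is a coarse stand-in for curved
  retinaculum-constrained tendon paths; l_OA/l_OB are effective constants
  chosen so the fascicle operates near optimal at neutral ankle.
* Electromechanical delay is rounded to whole samples at the model rate.
* The equilibrium is solved per sample (quasi-static force balance with a
  one-sample velocity memory), not as a continuous contraction-dynamics
  ODE; an ODE backend would matter at much higher rates or for stiff
  activation transients.
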