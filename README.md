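# hillfuse

Hill-type neuromuscular modelling of the human ankle plantarflexors with
**sensor fusion**: muscle activation is driven jointly by surface EMG and by
ultrasound-measured muscle thickness, and the model predicts the net ankle
plantarflexion moment over the walking stance phase across treadmill speeds.

The package is aimed at neuromuscular biomechanics and rehabilitation-robotics
researchers who want a calibratable, testable forward model of plantarflexion
moment — e.g. as the intent-estimation core of an exoskeleton or FES
controller — without requiring a motion-capture lab: a synthetic gait
generator with known ground truth makes every stage (signal conditioning,
activation dynamics, musculotendon equilibrium, calibration, prediction)
verifiable end to end.

## The model

Two muscle–tendon units (MTUs) are modelled: lateral gastrocnemius (LGS) and
soleus (SOL). For muscle *i* at sample *k*:

**Activation.** The normalized sEMG envelope `u_i` passes through a
second-order recursion with electromechanical delay τ,

    N_i(t_k) = α u_i(t_{k−τ}) − β₁ N_i(t_{k−1}) − β₂ N_i(t_{k−2}),
    β₁ = γ₁+γ₂,  β₂ = γ₁γ₂,  α − β₁ − β₂ = 1   (|γ| < 1),

then a nonlinear shape map `a₁ = (e^{A N} − 1)/(e^A − 1)` with A ∈ [−3, 0].
Ultrasound thickness gives `a₂ = (MT − MT_min)/(MT_max − MT_min)`, and the
fused drive is the convex combination

    a_i = δ_i a₁ + (1 − δ_i) a₂,   δ_i ∈ [0, 1].

δ = 1 is the pure sEMG-driven model, δ = 0 the pure ultrasound-driven one.

**Geometry and forces.** With the ankle modelled as a hinge, MTU length
follows the law of cosines, `l_mt = √(l_OA² + l_OB² − 2 l_OA l_OB cos q)`,
and the moment arm is its exact derivative `r = l_OA l_OB sin q / l_mt`.
The tendon obeys a piecewise force–strain law (quadratic toe to ξ = 0.0127,
linear above); the fascicle force is
`F = (F_max f_l(l̃) f_v(ṽ) a + F_max f_p(l̃)) cos φ` with pennation φ from
the constant-thickness assumption. At every sample the tendon length is
solved so tendon and fascicle force balance (bracketed root solve, residual
≤ 10⁻⁶ F_max), and the net moment is `M = Σ_i F_mt,i r_mt,i`.

**Calibration** minimizes the mean squared difference to an
inverse-dynamics benchmark moment over the stance samples of 10 steady gait
cycles (all from one speed, or two from each of five speeds), by bounded
least squares over `{A_i, l_t^sk_i, F_max,i, δ_i}` with slack length and
force boxed to 50–150 % of literature values.

## Worked example

```
python examples/04_fusion_benchmark.py
```

prints, for one synthetic subject (seed 1, inter-speed calibration):

```
held-out N-RMSE (% of peak moment), inter-speed calibration, seed 1:

variant  fused  semg_only  us_only
speed
0.50      1.72       1.78     6.49
0.75      2.90       3.15     5.63
1.00      1.89       2.20     5.81
1.25      2.51       2.86     3.72
1.50      2.51       2.90     4.78

means: fused 2.31%, semg_only 2.58%, us_only 5.29%

calibrated allocation gains: LGS delta = 0.80, SOL delta = 0.97
```

N-RMSE is the held-out prediction RMSE as a percent of the subject's peak
plantarflexion moment. Under the complementary-noise conditions (sEMG
cross-talk bursts, slow thickness-tracking wander) the fused model sits
below both single-modality variants at every speed: fusion averages away
error sources that neither channel can remove alone. The other examples
show the generator (`01`), the activation pathways (`02`) and noise-free
parameter recovery to numerical precision (`03`).

A thin CLI wraps the same library:
`hillfuse simulate|calibrate|predict|evaluate|compare` (see `--help`).

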