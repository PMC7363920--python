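# shoulderline

Shoulder-line orientation of walking pedestrians, estimated from overhead
depth imagelets — with the velocity direction of pre-existing trajectories
as free training labels — plus the stochastic-delay model that couples
velocity direction to body orientation.

## The problem

Body orientation ("yawing") is a key degree of freedom in crowd dynamics,
attention estimation and active-matter models of pedestrians, but it is hard
to measure in real life: manual annotation of overhead depth images is
expensive and unreliable.  Two physical facts make annotation unnecessary:

1. **Velocity is a weak label.**  While walking, the velocity direction θ_v
   is on average orthogonal to the shoulder line: θ = θ_v + ε with ε small,
   symmetric and zero-centered.  Orientation lives on the real projective
   line P¹(ℝ) (θ and θ + π are the same shoulder line), so the label space
   is angles modulo π.
2. **Averaging amends the noise.**  The estimator outputs a distribution
   h_pred over B = 45 orientation bins (soft-max head, trained with
   cross-entropy against two-hot targets h₂(θ_v)) and returns its P¹
   circular mean θ_o = 𝔼_{θ′∼h_pred}[θ′].  Under centered label noise the
   output converges to the conditional label distribution, whose circular
   mean is the *noise-free* orientation — training self-amends the labels:
   the aggregate bias b̂ = √(M⁻¹Σ b̂_k²) falls to ~0.005° even with σ = 20°
   label noise, while the ARMSE = M⁻¹Σ √(b̂_k² + V_k) measured against the
   noisy labels themselves saturates at the 20° noise floor.

Strict O(2) covariance, f(ΦR_α 𝓘) = (f(𝓘) + α)·det Φ, is enforced
post-hoc by group averaging: each prediction averages 2k evaluations (k
rotations, each with and without mirror) mapped back to the original frame
and combined with the P¹ circular mean.

Once orientations are measurable, the dynamics of the residual coupling can
be studied.  Velocity direction follows orientation with a fluctuating
delay, well described by

θ_v(t) = A·θ(t − d(t)),  ḋ = −(d − d̂)/τ + ξẆ  (Ornstein–Uhlenbeck),

with A = 1.85, d̂ = 0.08 s, τ = 1.2 s, ξ = 1.85 at normal walking speed.
The package simulates this model, estimates delays by windowed
cross-correlation with sub-sample refinement, and reproduces the standard
comparison panels (difference pdf, delay pdf, grand-average PSD).

Because no public dataset accompanies the method, the package ships a
first-class synthetic generator: two-ellipse depth imagelets (body +
head) whose ground-truth orientation is known by construction, and
orientation signals with gait sway (~0.8 Hz) and slow drift (~0.2 Hz).
See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from shoulderline import circular, dynamics, estimator, symmetry, synthgen

# --- train a compact estimator on weak labels ---------------------------
px, theta_gt, labels = synthgen.generate_imagelet_batch(
    6000, rng=0, size=32, pixel_pitch_m=0.04, noise_sd_deg=20.0)
training_set = estimator.build_training_set(px, labels)
net = estimator.NetworkConfig(imagelet_size=32,
                              conv_blocks=((8, 3, 2), (16, 3, 2), (32, 3, 2)),
                              dense_widths=(64,))
model = estimator.train(training_set, net, estimator.TrainingConfig(epochs=6, rng_seed=0))

test_px, test_gt, _ = synthgen.generate_imagelet_batch(
    2000, rng=1, size=32, pixel_pitch_m=0.04)
_, preds = model.predict_batch(test_px)
residuals = np.rad2deg(circular.p1_signed_diff(preds, test_gt))
print(f"plain estimator : bias {residuals.mean():+.3f} deg, "
      f"RMSE {np.sqrt((residuals**2).mean()):.2f} deg")

ga = symmetry.group_average_batch(model.predict_angles, test_px,
                                  model.background_mm,
                                  symmetry.GroupAverageConfig(k=8))
residuals_ga = np.rad2deg(circular.p1_signed_diff(ga, test_gt))
print(f"with k=8 average: bias {residuals_ga.mean():+.3f} deg, "
      f"RMSE {np.sqrt((residuals_ga**2).mean()):.2f} deg")

# --- orientation dynamics: recover the delay model from signals ---------
params = dynamics.reference_normal_walking()
pairs = []
for s in range(50):
    theta = synthgen.generate_orientation_signal(60.0, rng=100 + s)
    theta_v = dynamics.synthesize_velocity_direction(theta, params, rng=200 + s)
    pairs.append((theta, theta_v))
print(f"amplitude A recovered: {dynamics.recover_amplitude(pairs, params.d_hat_s):.2f} "
      f"(simulated with A = {params.A})")

delay = dynamics.simulate_ou_delay(params, 1000.0, rng=0)
print(f"OU delay: mean {delay.theta.mean()*1000:.0f} ms, "
      f"sd {delay.theta.std()*1000:.0f} ms")
```

Output:

```
plain estimator : bias +0.305 deg, RMSE 1.75 deg
with k=8 average: bias +0.038 deg, RMSE 0.85 deg
amplitude A recovered: 1.77 (simulated with A = 1.85)
OU delay: mean 84 ms, sd 116 ms
```

Reading the numbers: the estimator was trained on labels carrying 20° noise,
yet its error against noise-free ground truth is under 2°, and the O(2)
group average halves it again while removing most of the residual bias —
the self-amending property in action.  The dynamics half recovers the
coupling amplitude A and the ~100 ms mean delay of the simulated
orientation/velocity coupling from the signals alone.

A command-line surface wraps the same pipeline
(`shoulderline generate | train | predict | evaluate | learning-curve |
simulate | delay | compare`); every subcommand writes its artifacts
(16-bit PNG imagelets + CSV manifests, CSV signals and delay tables, JSON
summaries) with degrees/seconds/metres/millimetre units in the column
names.

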