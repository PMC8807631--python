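# socialtrack3d

3D body-model tracking of interacting mice from depth point clouds, with
downstream behavioral and neural analysis.

Studying social touch and "social receptive fields" in freely interacting
rodents requires knowing, frame by frame, where each animal's body, head and
nose are in 3D — through contact, crossing and mounting, when conventional
2D trackers lose identities. This package implements the full analysis chain
for such experiments:

1. **Body-model tracking.** Each mouse is a deformable pair of prolate
   spheroids (hip + head ellipsoid, spine-stretch coordinate `s`, optional
   head-implant sphere), giving 8 pose parameters per plain animal, 9 with
   an implant, 17 for the joint pose. Per frame, the weighted point cloud
   and detected body key-points are fit by minimizing a clipped-distance
   loss with overlap and identity-flip barriers, using an **annealed
   particle filter**: 200 quasi-random (Sobol) particles per body, all
   200×200 joint pairings scored at once, top-k resampling, 5 annealing
   iterations. Between frames an RLS filter bank proposes the next pose.
2. **State-space smoothing.** Constant-acceleration Kalman filtering with
   fixed-lag RTS smoothing of every skeleton landmark, 1D filtering of the
   spine stretch, and boxcar quaternion averaging of the body rotations.
3. **Behavioral features.** Egocentric speeds, social distances,
   template-matched social-touch events (nose↔nose, nose→tail), ear-based
   3D head direction, and a 45-column behavioral predictor matrix.
4. **Movement syllables.** Sticky Gaussian HMMs (5 locomotor states on
   forward/left speed, 3 rearing states on up speed) fit by MAP-EM with
   Viterbi decoding and bout statistics.
5. **Neural tuning.** Event-aligned PSTHs (naive and baseline-cleaned) with
   a modulation index, and a multiplexed Poisson tuning-curve model
   `λ = exp(Σ_p A_p c_p)/dt` with smoothness-penalized fits and greedy
   cross-validated forward selection of encoded features, plus a population
   co-encoding matrix.

A synthetic-scene generator (surface point clouds with camera-distance
weighting and occlusion, noisy typed key-points, scripted social episodes)
and a synthetic spike generator stand in for cameras, the key-point network
and electrodes, so the entire pipeline runs and is tested at desk scale.
Multi-camera calibration math (robust sphere fitting, rigid trajectory
alignment, arena detection) and LED/TTL clock synchronization (cross-
correlation + Theil–Sen drift fitting) are included.

## Worked example

```python
from socialtrack3d.pipeline import run_synthetic_benchmark

result = run_synthetic_benchmark(n_frames=300, points_per_frame=2000,
                                 n_particles=64, seed=1)
print(result)
```

prints (exact numbers depend on the seed):

```
{'median_error_mm': 1.606, 'p90_error_mm': 3.78, 'identity_accuracy': 1.0,
 'n_flags': 18, 'n_frames': 300, 'n_particles': 64}
```

meaning: on a 300-frame synthetic scene (~2000 cloud points/frame, 1 mm
surface noise, 2 mm key-point noise, 10% key-point dropout) the full
track-then-smooth pipeline recovers the skeleton landmarks of both animals
with a **median 3D error of 1.6 mm**, never swaps the two identities
(`identity_accuracy = 1.0`), and raises 18 per-frame anomaly flags (loss
spikes reviewed rather than trusted blindly).

Tracking a recorded frame container from the shell:

```bash
track --frames scene.h5 --out track.h5 --particles 200 --iters 5
```

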