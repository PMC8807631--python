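# Methods

This note documents the models and procedures implemented in `socialtrack3d`,
the assumptions behind them, and the numerical and design choices that were
genuinely open.

## Body model

Each mouse is modeled as two prolate spheroids joined at a neck joint: a
deformable **hip ellipsoid** and a rigid **head (nose) ellipsoid**. A spine
coordinate `s ∈ [0, 1]` morphs the hip ellipsoid between long-and-narrow
(`s = 1`: `a_hip = 25 mm`, `b_hip = 12 mm`) and short-and-wide (`s = 0`:
`a_hip = 5 mm`, `b_hip = 15 mm`). The neck joint sits at `d_hip = 0.75·a_hip`
along the hip major axis (the *s-dependent* `a_hip`, so a stretched body also
has a longer neck lever arm), and the head-ellipsoid center `d_nose = 10 mm`
beyond it along the head direction

    e_nose = (cos θ, sin θ cos φ, sin θ sin φ),

with θ and φ limited to a configurable neck cone (defaults ±π/2 and ±π/3; the
physical limit is not quantified anywhere authoritative, so these are
conservative round values). The hip orientation is `R(0, β, γ)` with the
convention `R(ax, ay, az) = Rz(az)·Ry(ay)·Rx(ax)`. An implanted animal
carries a rigid sphere (radius `0.9·b_nose`) attached to the head ellipsoid,
offset `x_impl` along and `z_impl` orthogonal to its major axis and free to
rotate about it by ψ — this ninth parameter captures head roll of the
implanted animal, which the rotationally symmetric ellipsoids cannot. All
lengths are SI meters internally; `body_scale` multiplies every length.

Pose parametrization: 8 free parameters for a plain animal
(x, y, z, β, γ, θ, φ, s), 9 with the implant (+ψ), 17 for the two-animal
joint pose.

**Approximate surface distance.** Exact point-to-ellipsoid distance requires
root-finding per point; the loss instead uses the distance along the ray
through the centroid, `d̃ = |1 − ‖p′‖_Q⁻¹|·‖p′‖` with `‖p′‖_Q² = p′ᵀQp′`.
This is exact for spheres and bounded on the 2:1 spheroids used here (the
test suite measures the worst case against a brute-force oracle; it stays
well below the minor axis, and the mean error is a small fraction of it). A
point exactly at the center maps to the smallest semi-axis — the limit of
the expression along any ray.

## Synthetic scenes

The generator stands in for the four-camera depth rig and the key-point
detection network. It emulates: surface point clouds sampled on the
body-model ellipsoids with per-point weights equal to the squared distance to
the generating virtual camera (points are assigned to cameras with
probability ∝ 1/d², reproducing the inverse-square density falloff);
camera-facing hemisphere occlusion; Gaussian surface noise (default 1 mm);
typed key-points (nose tip, tail pole, implant center, two ears) with jitter
(default 2 mm), independent dropout (default 10%), and uniform pseudo-
posteriors in [0.5, 1]. It does **not** emulate inter-body ray-cast
occlusion, sensor-specific noise (flying pixels, edge artifacts), or color
imagery — so passing tests demonstrate correctness of the fitting machinery
under realistic geometric noise, not robustness to every real-sensor
artifact.

Ear landmarks are not part of the body model proper; they are defined on the
head-ellipsoid surface at ±60° azimuth from the nose axis, raised 30°
dorsally. The elevation is what makes the ear-based head-direction estimate
(below) well-posed: perfectly lateral ears would average onto the nose axis.

Pose dynamics are keyframe choreography (PCHIP-interpolated) containing one
nose-to-nose and one directed nose-to-tail episode, plus band-limited
Gaussian jitter on every coordinate (σ = 6 mm positions / 0.08 rad angles,
bandwidth 20 frames at 60 Hz). These values were chosen once to give
mouse-like speeds (~0.1–0.5 m/s) and accelerations (~1 m/s²) at the
5–10-second scene lengths used throughout. A repair pass nudges hip centers
apart so no frame violates the overlap barrier. The per-frame container packs
each frame as a single jagged record — point coordinates (3N), weights (N),
key-point coordinates (3M), pseudo-posteriors (M), type codes (M), count
(1) — stored as variable-length rows in HDF5 with a JSON sidecar for the
configuration and ground truth.

## Tracking objective

Four loss contributions are evaluated for all m×n pairings of the two
bodies' candidate sets:

* **Point cloud**: Σᵢ wᵢ·min(dᵢ, 3 cm), where dᵢ is the smallest approximate
  distance to any surface of the candidate pair and wᵢ the squared camera
  distance. Clipping bounds any single outlier's contribution (clipped
  points contribute the clip value, not zero).
* **Key-points**: clipped distance from each key-point to its mapped
  landmark (nose→tip, tail→tail pole, implant→implant center, ears→head
  surface) on whichever body is closer; ties resolve to body 0 and cannot
  change the value. Detector pseudo-posteriors weight each term linearly by
  default (confidence weighting; can be disabled).
* **Overlap barrier**: a large constant (10⁶, hard-constraint semantics)
  whenever any cross-body pair of spheres — centered on the ellipsoids with
  radius equal to the minor axis — is strictly closer than 0.8× the sum of
  the radii.
* **Flip barrier**: the same condition between each body now and the *other*
  body in the previous frame, which pins identities through close contact.

The relative weight of the key-point term defaults to N/M (cloud points per
key-point) so both terms are of comparable scale per frame; it is
configurable. Batch evaluation is chunked over points to bound memory and is
bit-compatible with the naive per-pair loop (the central vectorization
oracle in the tests).

## Tracker

Within a frame, an annealed particle filter: each body proposes
`n_particles` candidates by scrambled-Sobol (low-discrepancy) perturbation of
its current candidates, the full m×n joint loss matrix is evaluated, and
top-k selection (partial `argpartition`, ties broken by flattened index)
keeps the best k pairings — duplicates of a row or column let the two body
subspaces collapse at different rates. Scales shrink geometrically by 0.5
per iteration over 5 iterations (the source material says only "smaller and
smaller"; a factor-2 geometric schedule is validated by the
convergence-within-5-iterations behavior in the tests). Initial scales are
1 cm / 0.3 rad / 0.1 stretch, sized to cover inter-frame motion at 60 fps.
The incumbent best pairing survives each iteration unperturbed, so the best
loss is non-increasing within a frame.

Between frames, a recursive-least-squares filter bank (time embedding 5,
forgetting factor μ = 0.99, regularization ε = 0.1) predicts the hip-center
x/y/z of both bodies; angular and stretch coordinates are carried over from
the last fit. The bank only trains for the first 150 frames. Because the
gain converges, a single outlier fit perturbs the next proposal by only
~20% of its displacement.

Tracking starts at the first frame whose key-points split into two k-means
clusters ≥ 5 cm apart, with initial headings from the nose/tail key-points
and ψ estimated from the implant key-point. Anomaly flags: frames with an
empty point cloud, losses above a rolling median + 5·MAD, and hip
displacements exceeding 1.5 m/s (above documented mouse locomotion; not a
measured constant). Tracking continues through flagged frames and recovers.

## Trajectory smoothing

Raw per-frame fits are smoothed in landmark space (the pose→3D map is
nonlinear, so smoothing pose parameters would distort trajectories): each
landmark runs through a constant-acceleration Kalman filter (state p, v, a
per axis; discrete white-noise process covariance) with fixed-lag (16-frame)
Rauch–Tung–Striebel smoothing; the spine stretch uses a 1D
position+velocity model and is clamped to [0, 1]; hip and head rotations are
recomputed from the smoothed `c_hip→c_mid` and `c_mid→c_nose` vectors
(the neck-to-nose-center reading — geometrically meaningful, since the two
vectors must be distinct to define the joint), converted to quaternions,
sign-aligned, and boxcar-averaged (10 frames) via the principal eigenvector
of the window's quaternion outer-product matrix. Nose tip and tail pole are
rebuilt from the smoothed centers, rotations, and spine stretch, so
`|c_mid − c_hip| = 0.75·a_hip(s)` and `|c_nose − c_mid| = d_nose` hold
exactly. Flagged frames are linearly interpolated in landmark space before
filtering.

Two calibration choices deserve emphasis:

* The initial state covariance is `σ_cov²·I` (identity). An all-ones
  covariance matrix is rank-1/singular and produces a ~100-frame transient.
* The default noise scales (`σ_meas = 15 mm`, `σ_process = 0.01`) describe a
  depth-sensor pipeline with centimeter-scale raw jitter and imply an
  acceleration noise far below real mouse dynamics; applied to any moving
  trajectory they cut corners by several millimeters.
  `KalmanConfig.for_synthetic_tracker()` therefore rescales them to the
  synthetic tracker's measured fit jitter (σ_meas = 3 mm) and body-scale
  accelerations (σ_process = 1 m/s²); the end-to-end benchmark uses this
  calibrated configuration. Both configurations are plain dataclasses; any
  deployment against a different sensor stack should re-measure its own raw
  jitter and set σ accordingly.

## Behavioral features and events

Egocentric speeds project the hip-center velocity (central differences,
dt = 1/60 s) on the horizontal forward axis, its left perpendicular, and
global z. Social distances are nose-tip↔nose-tip and the two directed
nose-tip↔tail-pole distances. Social events are template-matched:
nose-to-nose when the nose distance < 2 cm and both nose-tail distances
> 6 cm; a directed nose-to-tail contact when that nose-tail distance < 2 cm
and the nose-nose distance > 6 cm (contact means a *small* nose-tail
distance; a printed source figure states this condition with the inequality
inverted, which contradicts the configuration it describes). Each binary
trace is cleaned by binary opening (3 frames) then closing (30 frames);
runs become events.

The partner's 3D head direction comes from its ear key-points: ears are
assigned to the body whose head-ellipsoid center is closer *and* within
3 cm; the head-up vector is the unit rejection of the neck→ear-mean
direction from the nose axis, with σ = 3-frame Gaussian smoothing of the ear
mean and nose center, σ = 10 frames on the final vector. The implanted
animal's head-up vector comes directly from the implant offset.

The predictor matrix has exactly 45 named columns: 5 social (nose-nose
distance, two directed nose-tail distances, hip-center range rate, and the
signed horizontal orientation angle from the subject's head direction to the
partner's head center — negative when the partner is on the right) and 20
per animal: 7 posture (head yaw/pitch/roll, spine stretch, body pitch, hip
and nose height), 4 spatial (x, y, distance to wall, allocentric heading),
and 9 movement (the three egocentric speeds and central-difference
derivatives of the posture/heading angles and spine stretch). Angular
columns are wrapped to (−π, π]; the orientation angle and headings are
binned circularly. Derivatives use central differences throughout. No
column looks ahead beyond its symmetric smoothing window.

## Movement-syllable HMM

Locomotion (forward, left speed; centered and whitened per session) is
segmented with a 5-state Gaussian HMM, vertical speed with a 3-state 1D
model. Stickiness enters through the initialization
`T_init = (1 − η)I + η/K` (η = 0.05) and a sticky pseudo-count prior on the
transition rows. The reference fit is **MAP-EM** — deterministic and exactly
testable — with conjugate surrogates for the stated priors: Dirichlet-style
pseudo-counts (concentration 0.5 plus a diagonal stickiness count of 10) on
transitions and a normal–inverse-Wishart prior of matching scale
(κ₀ = 1 mean shrinkage toward 0 in whitened units, Ψ = 0.1·I) on the
emissions. Because every M-step is the exact maximizer of the penalized
expected complete-data log-likelihood, the penalized objective is provably
non-decreasing (asserted per iteration in the tests). Emissions are
initialized by k-means with a fixed seed; a state that empties is re-seeded
once and then flagged. Data enter as 600-frame snippets whose sufficient
statistics are pooled (equivalent to one weighted EM, not independent
models). Decoding is exact Viterbi; bouts are run-length encoded, and bout
statistics use two-sided Mann–Whitney U-tests plus the Spearman correlation
between bout-mean elevation and duration for the vertical model. State
matching for recovery evaluation pairs fitted and generating states by
nearest emission means.

## Neural analysis

**PSTHs.** Event-aligned rates with a "naive" variant (all events) and a
"cleaned" variant that keeps only events with no other detected social event
in the 4 s before onset. Baseline rate averages (−4, −2) s, response rate
(−0.5, 0.5) s; the paired two-tailed Wilcoxon signed-rank across events
tests for modulation, and the modulation index is
(r_post − r_pre)/(r_post + r_pre). Fewer than 5 usable events flags the
result under-powered.

**Multiplexed tuning model.** Spike counts per video frame (dt = 1/60 s)
are Poisson with rate `λ = exp(Σ_p A_p c_p)/dt`, where each feature enters
through a one-hot binned design matrix (10 bins; observed range for linear
features, (−π, π] for circular ones) and a tuning-curve vector — tuning is
multiplicative in rate space. Curves are fit by penalized maximum
likelihood: the penalty is β/2 times the squared *first difference* of each
curve (its gradient is the chain/circle graph Laplacian), with wrap-around
for circular features; β = 20 by default, calibrated once on synthetic
recovery (larger β visibly biases sparsely occupied edge bins; much smaller
β lets single-bin noise through). Optimization is trust-region Newton-CG
with analytic gradient and Hessian-vector products, tolerance 1e-3; the rate
exponent is clamped at 30 with a warning. The likelihood gain over the
constant-rate model is reported in bits/spike with both likelihood sums
normalized by the total spike count, signed so a better model is positive.

**Forward selection.** The session is split into 30 temporal chunks
assigned round-robin to 10 folds (so each fold's 3 test chunks are spread
across the session). Each round fits every one-feature-larger model on each
fold's 27 training chunks (all curves re-fit jointly), scores held-out
bits/spike against the current model, picks the best mean candidate, and
admits it if a one-sided exact Wilcoxon signed-rank over the 10 folds is
significant at 0.05; the first non-significant candidate stops the search.
An empty library is a valid outcome, and the stopping rule provides
per-round false-admission control (measured empirically on null simulations
in the tests). The 10 folds are 10 fixed disjoint assignments. Population
structure is summarized by the co-encoding matrix — counts of neurons whose
libraries contain both features — exported with a graph edge list.

## Camera calibration and synchronization

Pinhole deprojection/projection follows the standard intrinsics model with
nearest-integer rounding into the color image; zero depth is an invalid
pixel (NaN). The calibration ball is found by RANSAC sphere fitting with the
radius fixed at 40 mm (inlier threshold 2 mm — the order of depth-sensor
noise — 200 iterations, least-squares refit on inliers). Per-camera ball
trajectories are aligned by RANSAC over frame correspondences with an
orthogonal-Procrustes (Kabsch) refit on the consensus — robust to segments
where a camera lost the ball. Arena detection fits the dominant plane by
RANSAC (+ SVD refit), rotates its normal to +z, fits the wall cylinder as a
RANSAC circle in the horizontal plane, and masks points above the floor and
strictly inside the wall.

Clock synchronization between the LED blink trace (60 Hz) and TTL flips:
coarse alignment by first events, refinement by cross-correlation in 10 ms
steps, pairing of each TTL flip with the nearest detected blink, rejection
of pairs with |z| ≥ 2 (these are TTLs whose blink the camera missed — their
nearest-blink difference is off by a whole pulse gap), and a final Theil–Sen
regression of the pair differences on blink time for shift and drift. The
pairing direction matters: pairing blinks to TTLs instead would leave no
outliers to reject and let the cutoff clip genuine quantization noise
time-dependently, biasing the drift estimate. Pair counts are decimated to
6000 before Theil–Sen (quadratic cost); the simulated pulse train uses
150 ms pulses with uniform 150–350 ms gaps.

## Problem sizes and benchmark conditions

The end-to-end benchmark (also what `scripts/acceptance.py` runs) tracks a
300-frame scripted scene at ~2000 points/frame with 1 mm surface noise,
2 mm key-point noise and 10% key-point dropout, using 64 particles per body
and 5 annealing iterations — the reduced particle count keeps the benchmark
at desk scale; the loss machinery is also exercised at the full 200×200 =
40,000 joint pairings in the structural check. Test-suite simulations use
20,000 frames for HMM parameter recovery, 12,000 bins and 6 candidate
features for forward-selection recovery, and 2-hour pulse trains for drift
recovery; these sizes were chosen once as the smallest that give the
estimators their asymptotic behavior.

## Known limitations

* The tracker is built for exactly two animals (one implanted); the m×n
  pairing construction generalizes in principle but is not implemented for
  more bodies.
* Hemisphere culling approximates occlusion; real mutual occlusion during
  mounting/crawling is harsher than anything the generator produces.
* The MAP-EM HMM finds a local optimum; k-means initialization with a fixed
  seed makes it deterministic but not globally optimal.
* Whitening statistics for the HMM are per-session; cross-session syllable
  identity is not addressed.
* The forward-selection procedure inherits the multiplicative model's
  assumption of feature-separable log-rates; conjunctive (interaction)
  coding is out of scope.
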