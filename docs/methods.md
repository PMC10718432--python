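# Methods

## Rigid-body model

The arm and hand form a rooted kinematic tree of 16 segments carrying 23
revolute DOFs: shoulder adduction-abduction, flexion-extension and
internal-external rotation; elbow flexion-extension; forearm
pronation-supination; wrist flexion-extension and radial-ulnar deviation;
four thumb DOFs; and three flexion DOFs per finger. The thorax frame is
anchored at the reaching (right) glenohumeral joint, x anterior, y medial,
z up; gravity is (0, 0, −9.81) m/s². Exactly three DOFs are *dynamic*
during reaching — shoulder flexion-extension (measured from the
horizontal), shoulder internal-external rotation, elbow flexion-extension —
and the other twenty are held at the midpoint of their range of motion.
Shoulder flexion-extension spans ±90°, the elbow 0–150°, the fingers curl
to a relaxed mid-range posture; the full table lives in
`src/reachdyn/data/default_arm.yaml`.

Segment lengths scale linearly with subject height and masses with total
body mass through fixed anthropometric fractions (Winter / de Leva-style
regression tables): upper arm 0.186 H / 0.028 M, forearm 0.146 H / 0.016 M,
whole hand 0.108 H / 0.006 M, the hand mass subdivided over palm, thumb and
finger phalanges so that the static hand joints carry real gravity-holding
torques. Inertia tensors are diagonal rod-like approximations from the
tabulated radii of gyration (longitudinal radius = 0.25 × transverse). The
default subject is 1.8 m / 72.6 kg; the shipped configuration is plain YAML
and fully editable, and a model serializes to JSON bit-exactly.

## Movement synthesis

The workspace grid has 27 vertices indexed (anterior-posterior,
medio-lateral, vertical). The far-lateral column holds the outstretched-arm
anchor postures at −45°/0°/+45° shoulder elevation; the proximal plane sits
0.10 m anterior of the body's coronal plane; the medial column reaches
toward the front of the contralateral shoulder (0.17 × height medially);
middle vertices interpolate midway. Two geometric realities of a
3-dynamic-DOF chain shape the final grid:

* **"Outstretched" keeps ~10° of elbow flexion.** Full extension is both
  the boundary of the range of motion and a kinematic singularity (the
  internal-rotation endpoint gain vanishes), where exact path tracking
  demands unbounded joint accelerations. Natural reaching behaves the same
  way — the elbow never quite locks.
* **Medial clipping.** With shoulder abduction static, the elbow cannot
  leave the sagittal plane, so fingertip targets close to the contralateral
  shoulder at small anterior distances fall outside the reach envelope.
  The medial column is clipped to the least medial capacity across the
  three heights (a numeric search with a 5% margin), so that straight
  chords between medial vertices stay feasible; far-anterior coordinates
  are likewise capped by a reachability search.

Endpoint paths are straight segments with the minimum-jerk quintic profile
p(t) = p₀ + (p₁−p₀)(10s³ − 15s⁴ + 6s⁵), s = t/T, sampled at 1 ms for
durations 0.5/1.0/2.0 s; speed peaks at 1.875·D/T at mid-movement. All
C(27,2) = 351 unordered vertex pairs are enumerated per duration.

Per-sample inverse kinematics is a warm-started Newton iteration on the
3×3 Jacobian of the dynamic DOFs, compiled against a reduced chain (static
joints folded into fixed transforms). Where the chain is well-conditioned
(smallest singular value ≥ 0.045 m/rad) the solve runs to ~machine
precision — the tolerance is deliberately near 1e-12 m because the angles
are differentiated twice at 1 ms, which amplifies solver jitter by 4/dt².
Near the singular sheets (extension boundary; fingertip aligned with the
humerus in strongly folded postures) the solver switches to a
singularity-robust proximal update (Nakamura-style damping ramped as the
singular value drops, one damped update per sample) plus a 15 rad/s joint
speed cap. The endpoint then slips off the commanded chord — a median of
~2 mm, up to ~19 cm for the few fast proximal chords that run *along* a
sheet — in exchange for bounded, physiological joint kinematics; exact
tracking through a sheet would demand ~2500 rad/s² transients and
hundreds of N·m. Movements that stay clear of the sheets track to < 1e-6 m
at every step.

Joint angles are then low-pass filtered (4th-order zero-phase Butterworth,
10 Hz cutoff; reaching content at these durations lies below ~6 Hz), and
differentiated with central stencils — 6th-order in the interior, 4th- and
2nd-order in a few boundary samples, one-sided at the very ends. Static
DOFs receive exact zeros, never numerical derivatives.

## Inverse dynamics

Torques come from a recursive Newton–Euler pass in world coordinates:
outward recursion of angular velocity/acceleration and linear acceleration
(gravity as a fictitious −g base acceleration), inward accumulation of
forces and moments, τᵢ = ẑᵢ·nᵢ. The recursion is O(n) per sample and
vectorized over time. Verification is three-fold: a closed-form gravity
pendulum (agreement ~1e-15 N·m), a finite-difference Lagrangian oracle on
random 3-link spatial states (≤ 1e-5 N·m, FD-limited), and mechanical
power balance |τ·q′ − dE/dt| < 1e-3 W at every interior sample of the
generated movements (measured ≤ ~6e-6 W at 1 ms resolution with the
stencils above).

## Dataset

Each movement contributes per-sample state vectors [q, q′, q″, τ]. The 69
kinematic values reduce to 29 features (all 23 angles + dynamic velocities
and accelerations) by dropping the identically-zero static channels; a
configuration with every DOF dynamic keeps all 69. Splits are assigned to
whole trajectories — never samples — stratified by duration with
largest-remainder counting at 71/15/14; the manifest records exact counts,
seeds, feature layout and the model hash. Torque targets (and, by default,
input features) are z-scored with training-split statistics;
constant channels are flagged and passed through. Evaluation windows are
stride-1, within-trajectory, with the torque at the final sample as
target. Input noise is Gaussian with per-channel sd equal to the stated
fraction of that channel's peak-to-peak range over the test split, applied
to inputs only and regenerated from a recorded seed.

## Surrogate networks and training

Elman RNN, GRU and LSTM stacks (1/3/5 layers × 23/69/115 units, named
XXX-Y-ZZZ) with a linear readout to 23 torques, implemented in float32
numpy with hand-derived BPTT verified against finite differences to ~3e-10.
Input weights use uniform ±1/√H init, recurrent blocks are orthogonal per
gate. The optimizer is Adam at the canonical learning rates
{1e-4, 5e-4, 1e-3}. Two training modes:

* **stateful** (default): per-step loss over whole trajectories, truncated
  backpropagation in 100-sample chunks, mini-batches of 4 equal-length
  trajectories, the hidden state carried across chunks and reset to zero
  with probability 0.25 at chunk starts (exposing the net to the zero
  state it sees when evaluated on short windows);
* **window**: shuffled 256-window batches with loss on the final step.

Early stopping monitors validation MSE and returns the best-validation
parameters. The generic default patience is 10 epochs; the reduced-scale
experiment uses patience 25 within the 100-epoch cap, because its
8-movement validation estimate is noisy enough that patience 10 regularly
truncated training at a third of the budget. Everything is deterministic
given the seed; a single global seed fans out per stage by a CRC-32
derivation.

## Reduced-scale experiment and its honest limits

The headline experiment (`reachdyn.pipeline.reduced_gru_experiment`, also
driven by `scripts/acceptance.py`) uses the corner (2×2×2) subgrid at
0.5/1.0 s — 28 paths × 2 durations = 56 trajectories, ≈ 42,000 state
vectors — and trains GRU-1-115 in stateful mode. Typical results across
seeds: pooled test RMSE 0.38–0.56 N·m with 100-sample windows, rising by
1.03–1.11× under 1% input noise and 1.6–2.5× under 5%; RMSE is always
non-decreasing in the noise fraction.

These absolute errors should *not* be compared directly with full-scale
studies of the same task, for two measured reasons. First, the corner
corpus keeps only the longest chords (up to 1.2 m) at the fastest
durations, so its torque scale is large (shoulder flexion-extension sd
≈ 8 N·m, peaks ≈ 50 N·m). Second, with only ~40 training movements the
held-out chords traverse regions of state space the training set never
visits: an intentionally over-powered reference fit (2×256-unit MLP driven
to 0.017 N·m *training* RMSE on the same samples) still generalizes at
0.18 N·m, which bounds what any 115-unit surrogate can reach here. Both
constraints relax as the grid and duration coverage grow toward full
scale; the pipeline supports the full 3×3×3 × three-duration corpus
(1053 trajectories, ≈ 1.23 M state vectors, a few minutes of generation)
for users who want it.

Other known limitations: the synthetic corpus contains no via-points,
curved or object-interaction movements and no motor noise; the hand is a
fixed relaxed posture; the latency harness measures this numpy
implementation, not an optimized inference stack, and its numbers are
informational only.
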