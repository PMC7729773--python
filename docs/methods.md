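# Methods

## Problem and model

`posefall` recognises falls in 2D human-skeleton keypoint streams (the
BODY_25 layout produced by pose estimators such as OpenPose: 25 keypoints
per person as x, y, confidence triplets in image pixel coordinates, origin
top-left, y downward). A fall is modelled as a *state-transition process
with time continuity*: the body leaves a stable posture, remains unstable
for a sustained interval, and the geometry of that interval — how the
centroid moved, how active the lower limbs were, how disordered the
states were — separates real falls from confusing activities of daily
living (ADL) such as sitting down, squatting and bending over.

The pipeline has two stages.

### Stage one: per-frame state division

Six posture vectors are formed from the main torso: spine (neck 1 →
mid-hip 8), left/right thigh (hip → knee), left/right calf (knee →
ankle), and waist width (hip 9 → hip 12). Each segment's *deflection
angle* is the angle in [0°, 180°] between its vector and the up-image
vertical (0, −1), computed with the normalised dot product (argument
clipped to [−1, 1]); arms, wrists and feet are ignored because they carry
little weight-bearing information. The *spine ratio* |spine|/|waist| is a
monocular foreshortening cue: when the body pitches toward or away from
the camera the projected spine shortens while the waist width does not,
so the ratio collapses below 1 even though the deflection angles barely
move.

Two symbols integrate these features:

* **Tendency** — T1 if spine angle < ALL and ratio > RB; T3 if spine
  angle > AUL *or* ratio < RB; else T2. Defaults ALL = 30°, AUL = 50°,
  RB = 1.0.
* **Steady** — four angle *Pairs* are tested, each requiring both of its
  angles below AL = 30°: spine+left-thigh, spine+right-thigh,
  left-calf+left-thigh, right-calf+right-thigh. One true Pair gives S1,
  none gives S2.

The per-frame state is STABLE iff (T1, S1), DISORDER iff (T3, S2), else
FLUCTUATING, scored 0/1/2. All comparisons are strict, so boundary
equality falls to the middle/unsteady branch — this makes threshold
behaviour deterministic and testable. The T1/T3 ratio inequalities are
oriented so that a *low* ratio signals a falling tendency (a healthy
upright ratio is well above 1; camera-facing falls drive it below 1);
RB is configurable because values up to ≈1.2 are also defensible.

### Stage two: the NSRP detector

While stable, the detector refreshes a reference template
ξ = (Px, Py, H): mid-hip position and torso length H = ‖P1 − P8‖ at the
most recent stable frame. Three consecutive unstable frames open a
*non-stationary residence period* (NSRP). Inside it, three consecutive
stable frames abort the period (no event, template refreshed); otherwise,
once the 10-frame feature window following the trigger has elapsed, the
feature vector D = (γ, ε, τ) is computed and a classifier is queried
exactly once:

* γ = Σ μ with μ = softsign(Py − y₈) · ‖(Px, Py) − (x₈, y₈)‖ / H and
  softsign(x) = x/(1+|x|). μ < 0 when the mid-hip moved down-image;
  stable frames contribute μ = 0.
* ε = Σ over window frames and lower-limb keypoints {10, 11, 13, 14} of
  |y − ȳ|/H, the vertical dispersion of knees and ankles.
* τ = Σ of state scores (0 ≤ τ ≤ 2·window).

H is the template's frozen torso length, not the per-frame one — the
template exists precisely to provide a stable normaliser once the body is
already deforming. ξ is never updated inside a live NSRP (it is refreshed
on the abort frame and at stable frames while scanning).

Classification uses SVM (linear / polynomial / RBF kernel), K-nearest
neighbours, a decision tree, or a random forest, with stratified 3-fold
cross-validation for evaluation. Kernel scale p defaults to 1/3 (one over
the number of features), polynomial coef0 = 0 and degree = 3. The tree
uses the entropy criterion as the closest widely available approximation
of C4.5. Because γ, ε and τ live on scales an order of magnitude apart,
features are standardised (fit on training folds only) before SVM and
KNN; this is on by default and switchable.

## Design choices at genuinely open points

* **Feature window placement.** The feature window is the 10 frames
  *following* the 3 trigger frames; the trigger frames contribute to none
  of γ, ε, τ. Including them is available behind
  `DetectorConfig(include_trigger_frames=True)` since the alternative
  reading is defensible.
* **Tie-break.** If the window fills on the same frame that completes a
  stable run, the abort wins. The literal-transcription oracle in the
  test suite mirrors this, so the choice is pinned.
* **Dropout policy.** An invalid frame (missing torso keypoint below
  confidence 0.1, or waist width under 1 px) carries the previous state
  forward — before any valid frame the state is FLUCTUATING, never
  silently stable — and is skipped in γ/ε (coordinates are never
  fabricated) while still advancing the window and contributing its
  carried state to τ.
* **Post-event behaviour.** After an event (fall or not) all counters
  reset and the template waits for the next stable frame; no alarm
  cool-down is modelled.
* **Aggregate CV report.** Accuracy/precision/recall of a
  cross-validation report are fold means; its F1 is the harmonic mean of
  those means, so every report satisfies F1 = 2pr/(p+r) with its own
  fields.
* **Event spans** are reported as 0-based stream positions; the pipeline
  emits one entry per input frame (invalid ones included), so positions
  align with frame order.
* **Metric conventions.** `confusion_metrics` can treat either falls or
  non-falls as the positive class; accuracy is identical under both,
  while precision/recall swap roles. Both are reported by the CLI's
  count-table mode because published figures in this area do not always
  state the convention.

## The synthetic-motion generator

Real keypoint streams come from video; the generator instead animates a
stick figure (segment lengths: torso 100 px, hip width 40 px, thigh
0.55·torso, calf 0.45·torso; joint-angle trajectories; orthographic
projection) and renders full 25-keypoint frames. Six archetypes cover the
detector's operating envelope:

| action | spine angle | legs | mid-hip | spine ratio |
|---|---|---|---|---|
| WALK | 5°±5°, < 12.5° | alternating swing ≤ 16°, one quiet leg always | level | 2.5 |
| SIT_STAND | ramps to 40° (30–50° band) | thighs to 75° | dips 0.35·torso | > 1 |
| SQUAT | ≤ 24° | thighs to 80°, calves to 48° | dips 0.35·torso | > 1 |
| BEND | ramps to 70° | quiet (6°) | level | > 1 |
| LATERAL_FALL | all five angles ramp 8°→68° in 8 frames | follow spine | drops 0.85·torso | > 1 |
| FORWARD_FALL | stays < 30° | quiet | drops 0.8·torso | 2.5 → 0.625 |

The 12.5° walking bound is the postural-stability limit reported for
upright swaying; the 30°/50° bands mirror the stage-one thresholds so
that each archetype exercises a distinct decision path (BEND is
FLUCTUATING via T3+S1, SQUAT via T1+S2, FORWARD_FALL via the ratio
branch, LATERAL_FALL reaches DISORDER). Gaussian jitter (default sd 1 px
per coordinate) and optional keypoint dropout are applied after the
kinematics, so the kinematic contracts hold exactly only for the
noise-free skeleton; at 1 px jitter on ~100 px segments the induced angle
noise is ≈1°, far inside every threshold margin. Sequences default to 40
frames (≈1.6 s at 25 FPS); fall actions require ≥ 13 frames (trigger +
window). All randomness flows from a single integer seed;
`generate_corpus` derives per-sequence seeds deterministically and
returns both the sequences and the NSRP feature table (first event per
sequence).

What the generator does *not* emulate: pose-estimator noise structure
(correlated jitter, left/right swaps, identity switches), perspective
effects, limb self-occlusion during falls, and the variety of real human
kinematics. Synthetic separability of (γ, ε, τ) is therefore by
construction near-perfect, and passing tests demonstrate the pipeline's
correctness and internal consistency — not field accuracy on video data.

## Problem sizes and numerics

The test suite and the acceptance script run the pipeline at desk scale:
100-sequence corpora (≈40 frames each), 1000 random state streams for
the detector-equivalence check, 10⁴ random vectors for the angle-oracle
check (agreement to 1e-9°), 3-fold cross-validation on ~100 NSRP
samples. Angles are in degrees throughout; acos arguments are clipped to
[−1, 1]; the waist-width floor of 1 px and confidence floor of 0.1 guard
the spine-ratio denominator; a zero segment vector raises rather than
returning an arbitrary angle.

## Known limitations

* Single monitored subject; multi-person handling is greedy
  nearest-mid-hip tracking with no re-identification across long gaps.
* All window lengths are in frames; the defaults assume ≈25 FPS video
  and are not rate-adaptive.
* The entropy decision tree approximates C4.5 (no rule post-pruning,
  no native categorical splits).
* No alarm cool-down: a long disordered tail (a person remaining on the
  floor) can re-trigger further events; consumers should deduplicate by
  span if needed.
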