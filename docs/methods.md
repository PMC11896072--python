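# Methods

This note documents the models, conventions and design choices behind
`fms_aqa`, and what the shipped tests do and do not demonstrate.

## Skeleton model and coordinate conventions

A skeleton is one frame's 17 COCO-convention keypoints (nose, eyes, ears,
shoulders, elbows, wrists, hips, knees, ankles) with detector confidences
in [0, 1]. Two coordinate frames exist, tracked via `meta["frame"]`:

* **image** — raw pixels, y-down, as pose estimators emit them;
* **normalized** — y-up, divided by the torso length (mid-shoulder to
  mid-hip midpoint distance), no rotation or translation.

`normalize_skeleton` flips image input with `y ← (image_height − y)/scale`
and rescales; already-normalized input is only rescaled by its ≈ 1 torso,
making the operation idempotent. The y-up convention makes "hip lower than
knee" literally `y(hip) < y(knee)`. Torso length was chosen as the scale
unit because it is robust across the screened movements (the torso never
folds on itself in any FMS pattern) and preserves all inter-keypoint
angles; a zero-length torso raises a structured geometry error.

All scoring reduces to three primitives: `joint_angle` (arccos of the
normalized dot product of two joint-to-joint vectors, degrees in [0, 180],
symmetric, translation- and scale-invariant), `relative_position` (axis
ordering with a tie tolerance) and `joint_distance` (Euclidean, torso
units). Any primitive referencing a keypoint below the confidence floor
raises an "insufficient pose" error that the rule engine converts to an
*indeterminate* criterion entry — low-quality pose input degrades loudly,
never silently.

## Posture descriptor and keyframe selection

The posture scalar is Θ(s) = Σ_{i ≠ rightHip} cos ∠(v_rightHip, v_i),
with every position vector taken from the origin of the normalized frame
and the right-hip position vector as the reference direction. Two readings
of the published formulation exist: re-centering coordinates on the right
hip would make the reference vector itself zero and the expression
degenerate, so the descriptor is deliberately computed *without*
re-centering — the only reading under which it is well-defined. Likewise
the sum nominally runs over all 17 keypoints including the reference's own
term (identically 1); the implementation excludes the self term, and a
regression test asserts that including it in both the frame and the
standard descriptor shifts both by the same constant and cannot change any
distance or selected index.

The keyframe of a sequence is the frame minimizing the one-dimensional
distance |Θ_frame − Θ_N| to the movement's standard pose, ties broken by
the lowest frame index (the selection rule is silent on ties; earliest is
deterministic and favors the first attainment of the posture). Frames
whose descriptor cannot be computed are skipped with a warning; optional
per-movement angle/distance gates pre-filter candidates, and if a gate set
excludes every frame the selection falls back to the ungated argmin with a
warning rather than failing the trial (a gate is a hint, not a hard
contract, given gate thresholds ship as editable defaults).

Θ is scale-invariant but *not* translation-invariant; this is accepted
because all compared quantities (frames of one sequence and the standard
pose) are expressed in the same normalized frame, and the synthetic
generator builds standards and trials in that frame consistently.

## Rule base and score cascade

Rules are declarative YAML so per-movement thresholds can be transcribed
or edited without code changes. Each criterion carries: kind (angle /
position / distance), keypoints, comparator, threshold, the score level it
gates (3 or 2), a scoring-detail sentence, and body parts — the latter two
propagate verbatim into reports, prompts and rationales, preserving the
three-level annotation semantics (score → details → body parts).

The deep squat ships with the published score-3 criteria: trunk–shank
angle ("the trunk is parallel to the shins", operationalized as angle ≤
15°, configurable — "parallel" needs a tolerance to be decidable), hip
below knee, wrist right of knee (camera-frame right; whether subject- or
camera-frame right is intended is ambiguous, so it is configurable per
rule file). Every other movement's criteria and all level-2 thresholds are
structurally identical placeholders flagged `provenance: default`,
pending movement-specific expert thresholds; the engine is agnostic to
which movement a rule file describes.

Scores map by a hierarchical all-pass cascade: all level-3 criteria pass →
3, else all level-2 criteria pass → 2, else 1. This matches FMS manual
semantics (3 = clean execution, 2 = execution with compensation, 1 =
inability); the combination logic itself is a design choice, as published
sources describe criteria but not their combination. A level with no
criteria cannot be awarded (a rule file specifying only level-3 rows
yields 3 or 1). An indeterminate criterion at the level currently being
decided raises in strict mode; in lenient mode
(`allow_indeterminate`) that level is treated as not achieved, with a
logged warning. Score 0 (pain) requires subject report and is out of
scope for pose data.

## Prompting and backends

Prompt rendering is deterministic: a plain-text template per movement
(falling back to a shared default) with named placeholders for the rule
text, the measured indicator lines (angles to 1 decimal place), and any
single measurement (`measured_<criterion_id>`). Unknown placeholders fail
loudly naming the placeholder. Templates are versioned by content hash so
prompt changes are diffable and golden-tested.

The backend is a one-method contract (prompt → raw text). The shipped
`MockBackend` computes the cascade score on the report embedded in the
prompt and renders a rationale naming every violated criterion verbatim —
it exists so the full pipeline is exercisable and testable offline and
deterministically; with it, `assess()` is provably equivalent to the
deterministic cascade pipeline. Hosted-model adapters are intentionally
not bundled; `register_backend` accepts any object satisfying the
contract, and deterministic decoding settings are the adapter's
responsibility. Response parsing tolerates "Score: N", "…score is N" and a
leading bare digit, and fails (carrying the raw text) when no score in
{1, 2, 3} is present.

## Evaluation metrics

Accuracy, macro-F1 and Cohen's kappa are computed per movement plus an
average row. Scalar computations are delegated to scikit-learn; the test
suite checks them against an independent raw-counts contingency oracle to
1e-12. Policy choices owned here:

* macro-F1 averages over the classes observed in y_true ∪ y_pred (a
  movement in which experts assigned no 1s is not penalized with a zero
  F1 for an absent class); `fixed_classes=True` switches to always-{1,2,3}.
* Zero-division in precision/recall contributes 0.
* Degenerate kappa (both raters constant and identical, p_e = 1) is
  defined as 1.0 with a logged note — agreement is perfect even though the
  chance-correction quotient is undefined.
* The average row is the unweighted mean over movement rows by default;
  a pooled mode (recompute on all pairs concatenated) is provided since
  either reading of a summary row is defensible.

## Synthetic data generator

The generator defines the conditions every end-to-end test runs under.

* **Poses** are built by inverse construction in the normalized frame: the
  ankle anchors a shank of length 0.8 torso units at a per-movement tilt,
  the trunk vector is the shank direction rotated by the requested
  trunk–shank angle (so the measured angle equals the request exactly, to
  1e-6), hip height and wrist x-offsets realize the requested orderings
  (0.08 and 0.15 torso units by default — comfortably outside the 0.01
  tie tolerance), remaining keypoints come from a canonical side-view
  template, and the far body side is offset 0.04 units in depth. Torso
  length is exactly 1.
* **Sequences** embed a planted keyframe; off-peak frames interpolate
  toward a rest pose obtained by rotating the elbow and wrist keypoints
  about the descriptor-frame origin by `away_scale·|i − peak|` radians
  (default 0.04), in the direction that moves Θ away from the standard
  pose's Θ_N, clamped per keypoint. Because each moved cosine term is
  monotone in the rotation angle, the Θ-distance grows with |i − peak|
  and the planted frame is the unique argmin at zero noise — a provable
  property a straight-line coordinate interpolation would not give.
* **Noise** is isotropic per-keypoint Gaussian in normalized units, added
  after construction; confidences are Beta(8, 1) rescaled above a 0.5
  floor, with an optional dropout probability that plants 0.1-confidence
  keypoints to exercise the indeterminate path.
* **Datasets** emulate the real corpus structure — n subjects × 15
  movements (45 × 15 = 675 trials at the emulated scale), a score drawn
  per trial from a configurable distribution (uniform by default, as the
  per-movement score distribution of the source corpus is not published),
  a keyframe pose built to earn exactly that score under the rule base,
  and annotations carrying the three-level semantics. Generation is a
  pure function of (spec, seed), and the seed is recorded in outputs.

What passing on synthetic data shows — and does not. The generator plants
indicators exactly and varies them smoothly, so noiseless recovery of all
scores (accuracy = maF1 = kappa = 1.0 per movement) demonstrates the
pipeline's internal consistency: extraction finds the planted frame, the
engine measures what was planted, the cascade inverts the planting. It
does *not* demonstrate performance on real screening footage, where pose
estimators have structured (non-isotropic, occlusion-correlated) error,
real movements differ biomechanically between patterns, and expert labels
carry their own noise. Placeholder thresholds for the 14 non-deep-squat
movements would also need expert values before real use.

## Numerical and scale choices

* Angle cosines are clipped to [−1, 1] before arccos; zero-norm vectors
  (< 1e-9) raise rather than returning arbitrary angles.
* Tie tolerance for position orderings: 0.01 torso units (≈ 5 mm on a
  50 cm torso) — small enough to respect deliberate orderings, large
  enough to absorb detector jitter; configurable.
* Confidence floor 0.3, the conventional pose-estimator cut-off;
  configurable.
* Test problem sizes: the keyframe-selection oracle comparison runs 1,000
  random 50-frame sequences; metric oracles use 500 random label pairs;
  the end-to-end recovery runs the full 45 × 15 emulated corpus with
  30-frame trials; the noise sweep uses 20 seeds × 4 noise levels
  (0, 0.01, 0.05, 0.1 torso units) on 3 movements × 4 subjects. These
  sizes make the whole suite complete in seconds while keeping every
  check at or above the scale the claims are stated at.

## Known limitations

* 2-D, single-person skeletons only; no temporal smoothing, one keyframe
  per trial, no bilateral-asymmetry composite or 21-point FMS total.
* Θ collapses posture to one scalar; distinct postures can share a Θ
  value, and selection quality therefore leans on the standard poses and
  optional gates.
* Expert thresholds outside the deep squat ship as flagged defaults.
* The mock backend proves plumbing, not language-model behavior; results
  with a real model depend on the model and decoding settings.
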