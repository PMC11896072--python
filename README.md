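# fms-aqa

Fine-grained, interpretable scoring of Functional Movement Screen (FMS)
trials from 2-D pose keypoints.

The FMS is a sports-medicine screen of seven fundamental movement patterns
(deep squat, hurdle step, inline lunge, shoulder mobility, active straight
leg raise, trunk-stability push-up, rotary stability; 15 test movements
counting both sides), each graded 1–3 — higher means cleaner execution.
Automated FMS scorers built on end-to-end deep learning return a number but
no reason. This package implements the alternative: score from *explicit
expert rules* measured on the skeleton, so every grade comes with the
criteria it was decided on, the values measured, and the body parts
concerned.

It is for movement scientists, sports-medicine researchers and engineers
who already run an off-the-shelf pose estimator (any tool emitting COCO-17
keypoints per frame) and want reproducible, auditable FMS grades — plus a
synthetic-data generator that makes the whole pipeline testable without any
video or download.

## Method

Given a trial's skeleton sequence S = {k₁ … kₙ} (17 COCO keypoints per
frame, normalized to torso units, y-up):

1. **Keyframe selection.** Each frame is summarized by a posture scalar

   Θ(k) = Σ_{i ≠ rightHip} cos ∠(v_rightHip, v_i),

   the sum over the other 16 keypoints of the cosine of the angle between
   the right-hip position vector and each keypoint's position vector
   (Θ ∈ [−16, 16], scale-free). The scoring keyframe is
   k* = argmin |Θ(k) − Θ_N|, the frame closest to the expert standard
   pose's descriptor Θ_N; ties go to the earliest frame, and optional
   per-movement angle/distance gates can pre-filter candidates.
2. **Indicator extraction.** A declarative YAML rule base defines each
   movement's criteria — joint angles (e.g. the deep squat's trunk–shank
   angle θ₅₋₁₁,₁₃₋₁₅ between the shoulder→hip and knee→ankle vectors),
   relative positions (hip below knee; wrist right of knee), and joint
   distances — each tied to a score level, a scoring-detail sentence and
   the body parts it concerns. Every criterion is measured on k*;
   keypoints under the confidence floor yield *indeterminate* entries,
   never silent guesses.
3. **Scoring.** All level-3 criteria pass → 3; otherwise all level-2
   criteria pass → 2; otherwise 1 (score 0 — pain — requires subject
   report and is out of scope for pose data). The rules and measurements
   are also rendered into a prompt for a pluggable language-model backend;
   the shipped mock backend applies the same cascade deterministically, so
   the pipeline runs and tests fully offline.
4. **Evaluation.** Predicted vs expert scores per movement: accuracy
   N_correct/N_total, macro-F1 (unweighted mean of one-vs-rest F1 over the
   score classes), and Cohen's kappa (p₀ − p_e)/(1 − p_e) with p_e from
   the rater marginals, plus an average row.

## Worked example

```python
import fms_aqa as f

rulebase = f.default_rulebase()
spec = rulebase.spec("m01")                      # deep squat, side view

pose = f.make_pose(f.PoseRecipe(trunk_shank_angle_deg=22.0))
report = f.compute_indicators(pose, spec)
print(f.score_from_indicators(report, spec))
```

Running `python examples/02_rule_based_scoring.py` prints:

```
[level 3] angle_trunk_shank            measured=  22.0 degrees → FAIL  (The trunk is parallel to the shins.)
[level 3] hip_below_knee               measured=         below → pass  (Hip lower than knee.)
[level 3] wrist_right_of_knee          measured=      right of → pass  (The wrist joint is to the right of the knee joint.)
[level 2] angle_trunk_shank_relaxed    measured=  22.0 degrees → pass  (The trunk deviates only moderately from the shins.)
[level 2] hip_below_knee_compensated   measured=         below → pass  (Hip still descends below the knee.)

FMS score: 2
```

The 22.0° trunk–shank angle exceeds the 15° "parallel" tolerance required
for a 3 but stays inside the relaxed 30° tolerance, and both position
criteria hold — execution with compensation, score 2. The other scripts in
`examples/` walk through keyframe extraction (the selected index and its
Θ-distance), the full dataset evaluation table, and keypoint-file /
command-line usage. The `fms-aqa` CLI offers `simulate`, `extract-keyframes`,
`score` and `evaluate` subcommands over the same library calls.

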