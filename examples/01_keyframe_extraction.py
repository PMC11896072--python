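"""Select the scoring keyframe of a deep-squat trial.

Builds a synthetic 30-frame deep-squat sequence with the best-posture frame
planted at index 15, then selects the keyframe by posture-descriptor
distance to the movement's standard pose.
"""

import fms_aqa as f

rulebase = f.default_rulebase()
spec = rulebase.spec("m01")  # deep squat, side view

seq = f.make_sequence(spec.standard, n_frames=30, peak_index=15,
                      noise_sd=0.001, seed=7)
result = f.extract_keyframe(seq, spec.standard)

print(f"standard-pose descriptor  Θ_N = {spec.standard.theta_n.theta:.3f}")
print(f"selected keyframe index   = {result.index}")
print(f"descriptor distance |Θ−Θ_N| = {result.distance:.4f}")
print(f"Θ at first/selected/last frame: "
      f"{result.theta_trace[0]:.3f} / {result.theta_trace[result.index]:.3f} / "
      f"{result.theta_trace[-1]:.3f}")

# The descriptor Θ sums, over the 16 non-reference keypoints, the cosine of
# the angle between each keypoint's position vector and the right hip's; the
# selected index is the frame whose Θ lies closest to the standard pose's,
# i.e. the frame at which the scoring criteria should be measured.
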