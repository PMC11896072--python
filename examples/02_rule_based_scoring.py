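"""Measure expert scoring criteria on a keyframe pose and map them to a score.

Constructs a deep-squat keyframe with a 22° trunk–shank angle — outside the
15° "parallel" tolerance required for a 3, inside the relaxed 30° tolerance
for a 2 — and shows each measured criterion and the cascaded score.
"""

import fms_aqa as f
from fms_aqa.assess import format_measured

rulebase = f.default_rulebase()
spec = rulebase.spec("m01")

pose = f.make_pose(f.PoseRecipe(trunk_shank_angle_deg=22.0))
report = f.compute_indicators(pose, spec)

for entry in report.entries:
    status = {True: "pass", False: "FAIL", None: "indeterminate"}[entry.passed]
    print(f"[level {entry.level}] {entry.criterion_id:28s} "
          f"measured={format_measured(entry):>14} → {status}  ({entry.description})")

score = f.score_from_indicators(report, spec)
print(f"\nFMS score: {score}")
# Score 2: the level-3 angle criterion fails (22.0° > 15°) while every
# level-2 criterion passes — execution with compensation, not a clean squat.
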