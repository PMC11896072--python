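Deep squat trial (m01), assessed from the side view.
Keyframe index within the trial: 7

The deep squat screens bilateral, symmetrical mobility of the hips, knees
and ankles, with the dowel held overhead. Expert scoring rules:
Score 3 requires all of:
  - The trunk is parallel to the shins. (angle(left_shoulder, left_hip, left_knee, left_ankle) at most 15.0 degrees)
  - Hip lower than knee. (left_hip must be below left_knee (axis y))
  - The wrist joint is to the right of the knee joint. (left_wrist must be right of left_knee (axis x))
A trial meeting neither pattern scores 1.

Measured indicators at the selected keyframe:
- [level 3] The trunk is parallel to the shins. measured: 12.3 degrees; status: satisfied; body parts: Trunk, left lower limb, right lower limb
- [level 3] Hip lower than knee. measured: below; status: satisfied; body parts: left lower limb, right lower limb
- [level 3] The wrist joint is to the right of the knee joint. measured: right of; status: satisfied; body parts: Left upper limb, right upper limb, left lower limb, right lower limb

For reference, the measured trunk-shank angle is 12.3 degrees.

Grade this trial on the 1-3 FMS scale. Reply with a line "Score: N" and a
rationale that names each unmet criterion verbatim and offers one concrete
improvement suggestion per unmet criterion.
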