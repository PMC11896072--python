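Deep squat trial ({movement_id}), assessed from the {view} view.
Keyframe index within the trial: {keyframe_index}

The deep squat screens bilateral, symmetrical mobility of the hips, knees
and ankles, with the dowel held overhead. Expert scoring rules:
{rules_text}

Measured indicators at the selected keyframe:
{indicators_text}

For reference, the measured trunk-shank angle is {measured_angle_trunk_shank}.

Grade this trial on the 1-3 FMS scale. Reply with a line "Score: N" and a
rationale that names each unmet criterion verbatim and offers one concrete
improvement suggestion per unmet criterion.
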