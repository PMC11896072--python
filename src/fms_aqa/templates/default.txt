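Movement {movement_id} ({movement_name}), assessed from the {view} view.
Keyframe index within the trial: {keyframe_index}

Expert scoring rules for this movement:
{rules_text}

Measured indicators at the selected keyframe:
{indicators_text}

Grade this trial on the 1-3 FMS scale. Reply with a line "Score: N" and a
rationale that names each unmet criterion verbatim and offers one concrete
improvement suggestion per unmet criterion.
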