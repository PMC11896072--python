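version: 1
movements:
  m01:
    name: deep_squat
    view: side
    standard:
      keypoints:
        nose: [0.37, 2.178141929]
        left_eye: [0.34, 2.228141929]
        right_eye: [0.38, 2.228141929]
        left_ear: [0.29, 2.198141929]
        right_ear: [0.33, 2.208141929]
        left_shoulder: [0.25, 1.928141929]
        right_shoulder: [0.29, 1.928141929]
        left_elbow: [0.590960948, 1.642994066]
        right_elbow: [0.630960948, 1.642994066]
        left_wrist: [0.891921896, 1.257846202]
        right_wrist: [0.931921896, 1.257846202]
        left_hip: [0.491921896, 0.957846202]
        right_hip: [0.531921896, 0.957846202]
        left_knee: [0.741921896, 1.037846202]
        right_knee: [0.781921896, 1.037846202]
        left_ankle: [0.880840438, 0.25]
        right_ankle: [0.920840438, 0.25]
    criteria:
    - id: angle_trunk_shank
      kind: angle
      keypoints: [left_shoulder, left_hip, left_knee, left_ankle]
      comparator: within
      threshold: 15.0
      level: 3
      description: The trunk is parallel to the shins.
      body_parts: [Trunk, left lower limb, right lower limb]
      provenance: published
    - id: hip_below_knee
      kind: position
      keypoints: [left_hip, left_knee]
      axis: y
      comparator: ordering_equals
      threshold: below
      level: 3
      description: Hip lower than knee.
      body_parts: [left lower limb, right lower limb]
      provenance: published
    - id: wrist_right_of_knee
      kind: position
      keypoints: [left_wrist, left_knee]
      axis: x
      comparator: ordering_equals
      threshold: right_of
      level: 3
      description: The wrist joint is to the right of the knee joint.
      body_parts: [Left upper limb, right upper limb, left lower limb, right lower
          limb]
      provenance: published
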