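"""Synthetic skeleton sequences and labeled datasets.

Every other module is testable without any download because this module
builds 17-keypoint poses by *inverse construction*: the hip, knee, ankle,
shoulder and wrist are placed to realize a requested trunk–shank angle,
hip/knee height ordering and wrist/knee x-ordering exactly, and the
remaining keypoints are filled in from a canonical side-view template.
Sequences embed a planted keyframe whose posture-descriptor distance to the
standard pose grows with the distance from the planted frame, and datasets
emulate the real corpus structure: subjects × 15 movements, one score label
in {1, 2, 3} per trial, with per-frame Gaussian coordinate noise and
Beta-distributed detector confidences.

All randomness flows through one seeded NumPy generator; the seed is
recorded in every produced object's metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .errors import ConstructionError, ContractError
from .keyframe import StandardKeyframe, posture_theta
from .rules import MOVEMENT_IDS, Comparator, Criterion, MovementSpec, RuleBase
from .skeleton import (
    KEYPOINT_INDEX,
    PositionOrdering,
    Skeleton,
    SkeletonSequence,
)

_L = KEYPOINT_INDEX  # brevity

#: x-offset between the camera-near (left) and far (right) body side, in
#: torso units; a small depth shift keeps the two sides distinguishable.
SIDE_DEPTH = 0.04

#: Keypoints rotated about the descriptor-frame origin to move a frame's Θ
#: away from the planted keyframe's value.
_MOVERS = ("left_elbow", "right_elbow", "left_wrist", "right_wrist")

_MOVEMENT_NAMES = {
    "m01": "deep_squat",
    "m02": "hurdle_step_left",
    "m03": "hurdle_step_right",
    "m04": "inline_lunge_left",
    "m05": "inline_lunge_right",
    "m06": "shoulder_mobility_left",
    "m07": "shoulder_mobility_right",
    "m08": "active_straight_leg_raise_left",
    "m09": "active_straight_leg_raise_right",
    "m10": "trunk_stability_pushup",
    "m11": "rotary_stability_left",
    "m12": "rotary_stability_right",
    "m13": "shoulder_clearing",
    "m14": "spinal_extension_clearing",
    "m15": "spinal_flexion_clearing",
}

#: Movements assessed from the side camera; the rest use the front view.
_SIDE_VIEW = {"m01", "m02", "m03", "m04", "m05"}


class PoseRecipe(BaseModel):
    """Requested indicator values for one synthetic keyframe pose.

    ``trunk_shank_angle_deg`` is the angle between the shoulder→hip and
    knee→ankle vectors; ``hip_knee`` the hip-vs-knee height ordering;
    ``wrist_knee`` the wrist-vs-knee x ordering. Offsets are in torso
    units. ``shank_tilt_deg`` tilts the whole stance and is varied across
    movements so each movement has a distinct standard posture.
    """

    model_config = ConfigDict(frozen=True)

    movement_id: str = "m01"
    trunk_shank_angle_deg: float = 5.0
    hip_knee: PositionOrdering = PositionOrdering.BELOW
    wrist_knee: PositionOrdering = PositionOrdering.RIGHT_OF
    hip_offset: float = 0.08
    wrist_offset: float = 0.15
    shank_tilt_deg: float = 15.0
    noise_sd: float = 0.0
    seed: int = 0


def _rotation(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s], [s, c]])


def _confidences(
    rng: np.random.Generator | None,
    conf_floor: float = 0.5,
    low_conf_prob: float = 0.0,
) -> np.ndarray:
    """Detector-confidence vector: Beta(8, 1) rescaled above ``conf_floor``,
    with an optional probability of a dropped (0.1-confidence) keypoint."""
    if rng is None:
        return np.ones(17)
    conf = conf_floor + (1.0 - conf_floor) * rng.beta(8.0, 1.0, size=17)
    if low_conf_prob > 0:
        conf = np.where(rng.random(17) < low_conf_prob, 0.1, conf)
    return conf


def make_pose(
    recipe: PoseRecipe,
    rng: np.random.Generator | None = None,
    low_conf_prob: float = 0.0,
) -> Skeleton:
    """Build a skeleton whose measured indicators equal the recipe exactly
    (before noise).

    The stance faces camera-frame right (+x) in a y-up, torso-unit frame:
    the ankle anchors the shank, the trunk vector is the shank direction
    rotated by the requested angle, the hip sits above/below/level with the
    knee by ``hip_offset``, and the wrist sits left/right of/aligned with
    the knee by ``wrist_offset``. Torso length (mid-shoulder to mid-hip) is
    exactly 1 and the pose is tagged ``frame="normalized"``.
    """
    if not (0.0 <= recipe.trunk_shank_angle_deg <= 180.0):
        raise ConstructionError(
            f"trunk–shank angle {recipe.trunk_shank_angle_deg}° outside [0°, 180°]"
        )
    if recipe.noise_sd < 0:
        raise ConstructionError("noise_sd must be non-negative")
    if recipe.hip_knee not in (
        PositionOrdering.BELOW, PositionOrdering.ABOVE, PositionOrdering.LEVEL
    ):
        raise ConstructionError("hip_knee must be a y-axis ordering")
    if recipe.wrist_knee not in (
        PositionOrdering.LEFT_OF, PositionOrdering.RIGHT_OF, PositionOrdering.ALIGNED
    ):
        raise ConstructionError("wrist_knee must be an x-axis ordering")

    psi = math.radians(recipe.shank_tilt_deg)
    shank_dir = np.array([math.sin(psi), -math.cos(psi)])  # knee → ankle
    ankle = np.array([0.5, 0.1])
    knee = ankle - 0.8 * shank_dir

    hip_dy = {
        PositionOrdering.BELOW: -recipe.hip_offset,
        PositionOrdering.ABOVE: recipe.hip_offset,
        PositionOrdering.LEVEL: 0.0,
    }[recipe.hip_knee]
    hip = np.array([knee[0] - 0.25, knee[1] + hip_dy])

    trunk_dir = _rotation(recipe.trunk_shank_angle_deg) @ shank_dir  # shoulder → hip
    shoulder = hip - trunk_dir  # unit trunk ⇒ torso length exactly 1

    wrist_dx = {
        PositionOrdering.RIGHT_OF: recipe.wrist_offset,
        PositionOrdering.LEFT_OF: -recipe.wrist_offset,
        PositionOrdering.ALIGNED: 0.0,
    }[recipe.wrist_knee]
    wrist = np.array([knee[0] + wrist_dx, hip[1] + 0.3])
    elbow = (shoulder + wrist) / 2.0 + np.array([0.02, 0.05])

    nose = shoulder + np.array([0.12, 0.25])
    coords = np.zeros((17, 2))
    coords[_L["nose"]] = nose
    coords[_L["left_eye"]] = nose + np.array([-0.03, 0.05])
    coords[_L["right_eye"]] = nose + np.array([0.01, 0.05])
    coords[_L["left_ear"]] = nose + np.array([-0.08, 0.02])
    coords[_L["right_ear"]] = nose + np.array([-0.04, 0.03])
    depth = np.array([SIDE_DEPTH, 0.0])
    for side, off in (("left", 0.0), ("right", 1.0)):
        coords[_L[f"{side}_shoulder"]] = shoulder + off * depth
        coords[_L[f"{side}_elbow"]] = elbow + off * depth
        coords[_L[f"{side}_wrist"]] = wrist + off * depth
        coords[_L[f"{side}_hip"]] = hip + off * depth
        coords[_L[f"{side}_knee"]] = knee + off * depth
        coords[_L[f"{side}_ankle"]] = ankle + off * depth

    # Shift into the positive quadrant so every position vector from the
    # descriptor-frame origin has a comfortable norm.
    coords[:, 0] += 0.25 - coords[:, 0].min()
    coords[:, 1] += 0.25 - coords[:, 1].min()

    if recipe.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(recipe.seed)
        coords = coords + rng.normal(0.0, recipe.noise_sd, size=coords.shape)
    conf = _confidences(rng, low_conf_prob=low_conf_prob)
    return Skeleton(
        coords,
        conf,
        frame_index=0,
        meta={
            "frame": "normalized",
            "synthetic": True,
            "movement_id": recipe.movement_id,
            "seed": recipe.seed,
        },
    )


# ---------------------------------------------------------------------------
# Default rule base (deep-squat criteria published; the rest are editable
# placeholders pending movement-specific expert thresholds)


def _movement_recipe_defaults(movement_id: str) -> dict:
    idx = MOVEMENT_IDS.index(movement_id) + 1
    return {
        "shank_tilt_deg": 10.0 + 2.0 * (idx - 1),
        "trunk_shank_angle_deg": 3.0 + (idx % 7),
    }


def standard_pose(movement_id: str) -> Skeleton:
    """The expert-standard (score-3) pose for a movement, noise-free."""
    if movement_id not in MOVEMENT_IDS:
        raise ContractError(f"unknown movement id {movement_id!r}")
    recipe = PoseRecipe(movement_id=movement_id, **_movement_recipe_defaults(movement_id))
    return make_pose(recipe)


def _movement_criteria(movement_id: str) -> tuple[Criterion, ...]:
    published = movement_id == "m01"
    prov = "published" if published else "default"
    return (
        Criterion(
            id="angle_trunk_shank",
            kind="angle",
            keypoints=("left_shoulder", "left_hip", "left_knee", "left_ankle"),
            comparator=Comparator.WITHIN,
            threshold=15.0,
            level=3,
            description="The trunk is parallel to the shins.",
            body_parts=("Trunk", "left lower limb", "right lower limb"),
            provenance="published" if published else "default",
        ),
        Criterion(
            id="hip_below_knee",
            kind="position",
            keypoints=("left_hip", "left_knee"),
            axis="y",
            comparator=Comparator.ORDERING_EQUALS,
            threshold="below",
            level=3,
            description="Hip lower than knee.",
            body_parts=("left lower limb", "right lower limb"),
            provenance="published" if published else "default",
        ),
        Criterion(
            id="wrist_right_of_knee",
            kind="position",
            keypoints=("left_wrist", "left_knee"),
            axis="x",
            comparator=Comparator.ORDERING_EQUALS,
            threshold="right_of",
            level=3,
            description="The wrist joint is to the right of the knee joint.",
            body_parts=(
                "Left upper limb", "right upper limb",
                "left lower limb", "right lower limb",
            ),
            provenance="published" if published else "default",
        ),
        Criterion(
            id="angle_trunk_shank_relaxed",
            kind="angle",
            keypoints=("left_shoulder", "left_hip", "left_knee", "left_ankle"),
            comparator=Comparator.WITHIN,
            threshold=30.0,
            level=2,
            description="The trunk deviates only moderately from the shins.",
            body_parts=("Trunk", "left lower limb", "right lower limb"),
            provenance="default",
        ),
        Criterion(
            id="hip_below_knee_compensated",
            kind="position",
            keypoints=("left_hip", "left_knee"),
            axis="y",
            comparator=Comparator.ORDERING_EQUALS,
            threshold="below",
            level=2,
            description="Hip still descends below the knee.",
            body_parts=("left lower limb", "right lower limb"),
            provenance="default",
        ),
    )


def default_rulebase() -> RuleBase:
    """The shipped rule base for all 15 movements.

    The deep squat (m01) encodes the three published score-3 criteria
    verbatim; every other threshold and standard pose is a clearly-flagged
    editable default with the same structure.
    """
    movements = {}
    for mid in MOVEMENT_IDS:
        movements[mid] = MovementSpec(
            movement_id=mid,
            name=_MOVEMENT_NAMES[mid],
            view="side" if mid in _SIDE_VIEW else "front",
            standard=StandardKeyframe(mid, standard_pose(mid)),
            criteria=_movement_criteria(mid),
        )
    return RuleBase(movements=movements)


def plant_recipe(spec: MovementSpec, score: int, seed: int = 0) -> PoseRecipe:
    """A recipe whose pose earns exactly ``score`` under ``spec``'s cascade.

    Score 3 uses a trunk–shank angle well inside the level-3 tolerance;
    score 2 an angle between the level-3 and level-2 tolerances (so only
    level 3 fails); score 1 violates the level-2 angle and both position
    criteria.
    """
    if score not in (1, 2, 3):
        raise ContractError(f"score must be in {{1, 2, 3}}, got {score}")
    t3 = next(
        float(c.threshold) for c in spec.criteria_at(3) if c.kind == "angle"
    )
    t2 = next(
        (float(c.threshold) for c in spec.criteria_at(2) if c.kind == "angle"),
        t3 * 2.0,
    )
    base = _movement_recipe_defaults(spec.movement_id)
    if score == 3:
        angle, hip, wrist = t3 * 0.4, PositionOrdering.BELOW, PositionOrdering.RIGHT_OF
    elif score == 2:
        angle, hip, wrist = (t3 + t2) / 2.0, PositionOrdering.BELOW, PositionOrdering.RIGHT_OF
    else:
        angle = min(t2 + 12.0, 180.0)
        hip, wrist = PositionOrdering.ABOVE, PositionOrdering.LEFT_OF
    return PoseRecipe(
        movement_id=spec.movement_id,
        trunk_shank_angle_deg=angle,
        hip_knee=hip,
        wrist_knee=wrist,
        shank_tilt_deg=base["shank_tilt_deg"],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Sequences


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def make_sequence(
    std: StandardKeyframe,
    n_frames: int = 30,
    peak_index: int | None = None,
    away_scale: float = 0.04,
    noise_sd: float = 0.0,
    seed: int = 0,
    planted: Skeleton | None = None,
    subject_id: str = "synthetic",
    low_conf_prob: float = 0.0,
) -> SkeletonSequence:
    """Embed a planted keyframe pose in a sequence of off-peak frames.

    The frame at ``peak_index`` (default: middle) is the planted pose
    (``std``'s own skeleton unless ``planted`` overrides it, e.g. a pose
    built for a specific score). Off-peak frames interpolate toward a rest
    pose obtained by rotating the elbow and wrist keypoints about the
    descriptor-frame origin, by an angle ``away_scale·|i − peak|`` radians
    (clamped per keypoint to preserve monotonicity). The rotation direction
    moves each frame's Θ strictly away from the standard pose's Θ_N, so at
    ``noise_sd = 0`` the Θ-distance grows with |i − peak| and the planted
    frame is the unique argmin. Gaussian coordinate noise and Beta-drawn
    confidences are applied per frame afterwards; the same seed yields an
    identical sequence.
    """
    if n_frames < 1:
        raise ContractError("n_frames must be ≥ 1")
    if peak_index is None:
        peak_index = n_frames // 2
    if not (0 <= peak_index < n_frames):
        raise ContractError(
            f"peak_index {peak_index} outside [0, {n_frames})"
        )
    if away_scale < 0 or noise_sd < 0:
        raise ContractError("away_scale and noise_sd must be non-negative")

    base = planted if planted is not None else std.skeleton
    theta_p = posture_theta(base).theta
    theta_n = std.theta_n.theta
    # Move Θ away from Θ_N: lower it when the planted pose already sits at
    # or below the standard, raise it otherwise.
    decrease = theta_p <= theta_n

    hip = base.coords[KEYPOINT_INDEX["right_hip"]]
    phi_hip = math.atan2(hip[1], hip[0])
    movers = []
    margin = 0.02
    for name in _MOVERS:
        k = KEYPOINT_INDEX[name]
        x, y = base.coords[k]
        offset = _wrap_angle(math.atan2(y, x) - phi_hip)
        if decrease:
            sign = 1.0 if offset >= 0 else -1.0
            headroom = max(0.0, math.pi - abs(offset) - margin)
        else:
            sign = -1.0 if offset > 0 else 1.0
            headroom = max(0.0, abs(offset) - margin)
        movers.append((k, sign, headroom))

    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        coords = base.coords.copy()
        delta = away_scale * abs(i - peak_index)
        if delta > 0:
            for k, sign, headroom in movers:
                d = sign * min(delta, headroom)
                c, s = math.cos(d), math.sin(d)
                x, y = coords[k]
                coords[k] = (c * x - s * y, s * x + c * y)
        if noise_sd > 0:
            coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
        conf = _confidences(rng if (noise_sd > 0 or low_conf_prob > 0) else None,
                            low_conf_prob=low_conf_prob)
        frames.append(
            Skeleton(coords, conf, frame_index=i,
                     meta={"frame": "normalized", "synthetic": True})
        )
    return SkeletonSequence(
        frames=tuple(frames),
        movement_id=std.movement_id,
        subject_id=subject_id,
        meta={"seed": seed, "peak_index": peak_index, "noise_sd": noise_sd},
    )


# ---------------------------------------------------------------------------
# Datasets


class Annotation(BaseModel):
    """Ground-truth record mirroring the three-level semantic structure:
    score, scoring details, and the body parts those details concern."""

    model_config = ConfigDict(frozen=True)

    subject_id: str
    movement_id: str
    score: int
    scoring_details: tuple[str, ...] = ()
    body_parts: tuple[str, ...] = ()


class SyntheticDatasetSpec(BaseModel):
    """Shape of a generated dataset: subjects × movements with a score
    distribution over {1, 2, 3} and per-sequence embedding parameters."""

    model_config = ConfigDict(frozen=True)

    n_subjects: int = 45
    movements: tuple[str, ...] = MOVEMENT_IDS
    score_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_frames: int = 30
    peak_index: int | None = None
    away_scale: float = 0.04
    noise_sd: float = 0.0
    low_conf_prob: float = 0.0
    seed: int = 0

    def validate_spec(self) -> None:
        if self.n_subjects < 1:
            raise ContractError("n_subjects must be ≥ 1")
        unknown = [m for m in self.movements if m not in MOVEMENT_IDS]
        if unknown:
            raise ContractError(f"unknown movement id(s): {unknown}")
        if abs(sum(self.score_probs) - 1.0) > 1e-9 or min(self.score_probs) < 0:
            raise ContractError("score_probs must be a distribution over {1,2,3}")
        if self.n_frames < 1:
            raise ContractError("n_frames must be ≥ 1")
        if self.peak_index is not None and not (0 <= self.peak_index < self.n_frames):
            raise ContractError("peak_index must lie within [0, n_frames)")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticSample:
    sequence: SkeletonSequence
    annotation: Annotation
    planted_keyframe: int


@dataclass(frozen=True)
class SyntheticDataset:
    spec: SyntheticDatasetSpec
    samples: tuple[SyntheticSample, ...]
    meta: dict = field(default_factory=dict)

    @property
    def sequences(self) -> tuple[SkeletonSequence, ...]:
        return tuple(s.sequence for s in self.samples)

    @property
    def annotations(self) -> tuple[Annotation, ...]:
        return tuple(s.annotation for s in self.samples)


def _annotation_for(spec: MovementSpec, subject_id: str, score: int) -> Annotation:
    if score == 3:
        criteria: TypingSequence[Criterion] = spec.criteria_at(3)
    elif score == 2:
        criteria = spec.criteria_at(2)
    else:
        criteria = spec.criteria
    details = tuple(dict.fromkeys(c.description for c in criteria))
    parts = tuple(dict.fromkeys(p for c in criteria for p in c.body_parts))
    return Annotation(
        subject_id=subject_id,
        movement_id=spec.movement_id,
        score=score,
        scoring_details=details,
        body_parts=parts,
    )


def make_dataset(
    dataset_spec: SyntheticDatasetSpec,
    rulebase: RuleBase | None = None,
) -> SyntheticDataset:
    """Generate a labeled dataset: one sequence per (subject, movement).

    For each trial a score is drawn from the score distribution, a keyframe
    pose is built to satisfy exactly that score's criteria pattern under
    the rule base, and the pose is embedded at the planted keyframe
    position of a sequence. Annotations carry score, scoring details and
    body parts. Generation is a pure function of (spec, seed).
    """
    dataset_spec.validate_spec()
    if rulebase is None:
        rulebase = default_rulebase()
    root = np.random.default_rng(dataset_spec.seed)
    samples = []
    for s in range(dataset_spec.n_subjects):
        subject_id = f"s{s + 1:03d}"
        for mid in dataset_spec.movements:
            mspec = rulebase.spec(mid)
            score = int(root.choice((1, 2, 3), p=dataset_spec.score_probs))
            child_seed = int(root.integers(0, 2**31 - 1))
            pose = make_pose(plant_recipe(mspec, score, seed=child_seed))
            peak = (
                dataset_spec.peak_index
                if dataset_spec.peak_index is not None
                else dataset_spec.n_frames // 2
            )
            seq = make_sequence(
                mspec.standard,
                n_frames=dataset_spec.n_frames,
                peak_index=peak,
                away_scale=dataset_spec.away_scale,
                noise_sd=dataset_spec.noise_sd,
                seed=child_seed,
                planted=pose,
                subject_id=subject_id,
                low_conf_prob=dataset_spec.low_conf_prob,
            )
            samples.append(
                SyntheticSample(
                    sequence=seq,
                    annotation=_annotation_for(mspec, subject_id, score),
                    planted_keyframe=peak,
                )
            )
    return SyntheticDataset(
        spec=dataset_spec,
        samples=tuple(samples),
        meta={"seed": dataset_spec.seed},
    )
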