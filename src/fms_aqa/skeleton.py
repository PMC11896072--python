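"""Skeleton data model and geometric primitives.

A :class:`Skeleton` is one frame's 17 COCO keypoints (2-D, with detector
confidences). All scoring rules reduce to three primitives on a skeleton:

* :func:`joint_angle` — the angle between two joint-to-joint vectors,
  e.g. the trunk–shank angle between the shoulder→hip and knee→ankle vectors;
* :func:`relative_position` — the ordering of two joints along one axis
  (hip below knee, wrist right of knee), with a tie tolerance;
* :func:`joint_distance` — the Euclidean distance between two joints.

Internally all frames are y-up, so "hip lower than knee" literally means
``y(hip) < y(knee)``. Image-coordinate (y-down) input is flipped once at
normalization time and tagged via ``meta["frame"]``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .errors import ContractError, GeometryError, InsufficientPoseError

#: The 17 keypoint names of the COCO convention, in canonical order.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

RIGHT_HIP = KEYPOINT_INDEX["right_hip"]

#: Default detector-confidence floor below which a keypoint is unusable.
DEFAULT_MIN_CONFIDENCE = 0.3

#: Default tie tolerance for position orderings, in normalized units.
DEFAULT_TIE_TOL = 0.01


class PositionOrdering(str, enum.Enum):
    """Relative position of keypoint i with respect to keypoint j on one axis."""

    BELOW = "below"
    ABOVE = "above"
    LEVEL = "level"
    LEFT_OF = "left_of"
    RIGHT_OF = "right_of"
    ALIGNED = "aligned"

    def mirrored(self) -> "PositionOrdering":
        """The ordering of (j, i) given the ordering of (i, j)."""
        return _MIRROR[self]


_MIRROR = {
    PositionOrdering.BELOW: PositionOrdering.ABOVE,
    PositionOrdering.ABOVE: PositionOrdering.BELOW,
    PositionOrdering.LEVEL: PositionOrdering.LEVEL,
    PositionOrdering.LEFT_OF: PositionOrdering.RIGHT_OF,
    PositionOrdering.RIGHT_OF: PositionOrdering.LEFT_OF,
    PositionOrdering.ALIGNED: PositionOrdering.ALIGNED,
}


@dataclass(frozen=True)
class Keypoint:
    """One named 2-D keypoint with a detector confidence in [0, 1]."""

    name: str
    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in KEYPOINT_INDEX:
            raise ContractError(f"unknown keypoint name {self.name!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ContractError(f"non-finite coordinates for keypoint {self.name!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ContractError(
                f"confidence {self.confidence} for {self.name!r} outside [0, 1]"
            )


@dataclass(frozen=True)
class Skeleton:
    """One frame's 17 keypoints in fixed COCO order.

    ``coords`` is a (17, 2) float array, ``confidence`` a (17,) float array
    aligned with :data:`COCO_KEYPOINTS`. ``meta["frame"]`` records the
    coordinate convention: ``"image"`` (pixels, y-down) or ``"normalized"``
    (torso-scaled, y-up).
    """

    coords: np.ndarray
    confidence: np.ndarray
    frame_index: int = 0
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        conf = np.asarray(self.confidence, dtype=float)
        if coords.shape != (17, 2):
            raise ContractError(f"expected (17, 2) coordinates, got {coords.shape}")
        if conf.shape != (17,):
            raise ContractError(f"expected 17 confidences, got {conf.shape}")
        if not np.all(np.isfinite(coords)):
            raise ContractError("skeleton contains non-finite coordinates")
        if np.any(conf < 0) or np.any(conf > 1):
            raise ContractError("confidence values outside [0, 1]")
        if self.frame_index < 0:
            raise ContractError("frame_index must be non-negative")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "confidence", conf)

    @classmethod
    def from_keypoints(
        cls,
        keypoints: list[Keypoint],
        frame_index: int = 0,
        meta: Mapping[str, object] | None = None,
    ) -> "Skeleton":
        if len(keypoints) != 17:
            raise ContractError(f"expected 17 keypoints, got {len(keypoints)}")
        names = [kp.name for kp in keypoints]
        if names != list(COCO_KEYPOINTS):
            if sorted(names) == sorted(COCO_KEYPOINTS):
                raise ContractError("keypoints out of canonical COCO order")
            raise ContractError("keypoint names are not the 17 COCO names")
        coords = np.array([[kp.x, kp.y] for kp in keypoints], dtype=float)
        conf = np.array([kp.confidence for kp in keypoints], dtype=float)
        return cls(coords, conf, frame_index, dict(meta or {}))

    def keypoint(self, name: str) -> Keypoint:
        i = self._index(name)
        return Keypoint(name, *self.coords[i], self.confidence[i])

    def __iter__(self) -> Iterator[Keypoint]:
        for name in COCO_KEYPOINTS:
            yield self.keypoint(name)

    @staticmethod
    def _index(name: str) -> int:
        try:
            return KEYPOINT_INDEX[name]
        except KeyError:
            raise ContractError(f"unknown keypoint name {name!r}") from None

    def point(self, name: str, min_confidence: float | None = None) -> np.ndarray:
        """Coordinates of a named keypoint, gated on confidence."""
        i = self._index(name)
        if min_confidence is not None and self.confidence[i] < min_confidence:
            raise InsufficientPoseError(
                f"keypoint {name!r} has confidence "
                f"{self.confidence[i]:.3f} < {min_confidence:.3f}",
                keypoint=name,
            )
        return self.coords[i]

    def torso_length(self) -> float:
        """Distance from mid-shoulder to mid-hip (the normalization scale)."""
        mid_shoulder = (
            self.coords[KEYPOINT_INDEX["left_shoulder"]]
            + self.coords[KEYPOINT_INDEX["right_shoulder"]]
        ) / 2.0
        mid_hip = (
            self.coords[KEYPOINT_INDEX["left_hip"]]
            + self.coords[KEYPOINT_INDEX["right_hip"]]
        ) / 2.0
        return float(np.linalg.norm(mid_shoulder - mid_hip))

    def is_normalized(self) -> bool:
        return self.meta.get("frame") == "normalized"


@dataclass(frozen=True)
class SkeletonSequence:
    """An ordered run of skeleton frames for one (subject, movement) trial."""

    frames: tuple[Skeleton, ...]
    movement_id: str
    subject_id: str = "anonymous"
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ContractError("SkeletonSequence requires at least one frame")
        indices = [f.frame_index for f in frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ContractError("frame_index must be strictly increasing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Skeleton]:
        return iter(self.frames)


def normalize_skeleton(raw: Skeleton, image_height: float) -> Skeleton:
    """Rescale a skeleton to torso units and flip image input to y-up.

    Image-frame input (``meta["frame"] != "normalized"``) is flipped with
    ``y_norm = (image_height − y_pixel) / scale``; already-normalized input
    is only rescaled by its torso length (≈ 1), making the operation
    idempotent to floating-point precision. No rotation or translation is
    applied, so all inter-keypoint angles are preserved.

    Raises
    ------
    GeometryError
        If the torso (mid-shoulder to mid-hip) has zero length.
    """
    scale = raw.torso_length()
    if scale <= 1e-12:
        raise GeometryError(
            "degenerate torso: mid-shoulder and mid-hip coincide; "
            "cannot establish a normalization scale"
        )
    coords = raw.coords.copy()
    if not raw.is_normalized():
        coords[:, 1] = image_height - coords[:, 1]
    coords /= scale
    meta = dict(raw.meta)
    meta["frame"] = "normalized"
    meta.setdefault("norm_scale", scale)
    return replace(raw, coords=coords, meta=meta)


def _vector(
    s: Skeleton, tail: str, head: str, min_confidence: float | None
) -> np.ndarray:
    v = s.point(head, min_confidence) - s.point(tail, min_confidence)
    if float(np.linalg.norm(v)) <= 1e-9:
        raise GeometryError(
            f"zero-length vector between keypoints {tail!r} and {head!r}"
        )
    return v


def joint_angle(
    s: Skeleton,
    a: str,
    b: str,
    c: str,
    d: str,
    min_confidence: float | None = DEFAULT_MIN_CONFIDENCE,
) -> float:
    """Angle in degrees, in [0, 180], between vectors (b − a) and (d − c).

    The deep-squat trunk–shank angle is ``joint_angle(s, "left_shoulder",
    "left_hip", "left_knee", "left_ankle")``: the angle between the
    shoulder→hip (trunk) and knee→ankle (shank) vectors; 0° means the trunk
    is parallel to the shins. Symmetric under swapping the two vectors and
    invariant to translation and positive scaling.
    """
    u = _vector(s, a, b, min_confidence)
    v = _vector(s, c, d, min_confidence)
    cosine = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    cosine = min(1.0, max(-1.0, cosine))
    return math.degrees(math.acos(cosine))


def relative_position(
    s: Skeleton,
    i: str,
    j: str,
    axis: str,
    tie_tol: float = DEFAULT_TIE_TOL,
    min_confidence: float | None = DEFAULT_MIN_CONFIDENCE,
) -> PositionOrdering:
    """Ordering of keypoint ``i`` relative to ``j`` along ``axis``.

    On axis ``"y"`` (y-up): ``below`` / ``above`` / ``level``. On axis
    ``"x"``: ``left_of`` / ``right_of`` / ``aligned``, with larger x being
    camera-frame right. Differences of magnitude ≤ ``tie_tol`` are ties.
    """
    if axis not in ("x", "y"):
        raise ContractError(f"axis must be 'x' or 'y', got {axis!r}")
    if tie_tol < 0:
        raise ContractError("tie_tol must be non-negative")
    k = 0 if axis == "x" else 1
    vi = float(s.point(i, min_confidence)[k])
    vj = float(s.point(j, min_confidence)[k])
    if axis == "y":
        if vi < vj - tie_tol:
            return PositionOrdering.BELOW
        if vi > vj + tie_tol:
            return PositionOrdering.ABOVE
        return PositionOrdering.LEVEL
    if vi < vj - tie_tol:
        return PositionOrdering.LEFT_OF
    if vi > vj + tie_tol:
        return PositionOrdering.RIGHT_OF
    return PositionOrdering.ALIGNED


def joint_distance(
    s: Skeleton,
    i: str,
    j: str,
    min_confidence: float | None = DEFAULT_MIN_CONFIDENCE,
) -> float:
    """Euclidean distance between two keypoints, in the skeleton's units."""
    return float(
        np.linalg.norm(s.point(i, min_confidence) - s.point(j, min_confidence))
    )
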