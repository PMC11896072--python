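"""Posture descriptor and keyframe selection.

The scoring pipeline evaluates one *keyframe* per trial: the frame whose
posture best matches an expert-selected standard pose for that movement.
Posture is summarized by a single scalar

    Θ(s) = Σ_{i ≠ right_hip} cos ∠( v_rightHip , v_i )

where v_j is keypoint j's position vector from the origin of the
scale-normalized, y-up frame, and the right-hip position vector serves as
the reference direction. Θ is dimensionless, lies in [−16, 16], and is
invariant to positive scaling of all coordinates (cosines are scale-free).
The keyframe is the frame minimizing the one-dimensional Euclidean distance
D = |Θ_frame − Θ_standard|, ties broken by lowest frame index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ExtractionError, GeometryError
from .skeleton import RIGHT_HIP, Skeleton, SkeletonSequence, joint_angle, joint_distance

logger = logging.getLogger(__name__)

#: Number of cosine terms in the descriptor (all keypoints except the
#: right-hip reference itself).
N_DESCRIPTOR_TERMS = 16


@dataclass(frozen=True)
class PostureDescriptor:
    """Sum-of-cosines posture scalar Θ with its term count."""

    theta: float
    n_terms: int = N_DESCRIPTOR_TERMS

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ContractError("theta must be finite")
        if abs(self.theta) > self.n_terms + 1e-9:
            raise ContractError(
                f"theta {self.theta} outside [-{self.n_terms}, {self.n_terms}]"
            )


@dataclass(frozen=True)
class SelectionGate:
    """Optional per-movement pre-filter on candidate keyframes.

    A frame is a candidate only if the gated quantity (a joint angle in
    degrees or a joint distance in normalized units) lies in
    [min_value, max_value]. Gates encode the expert threshold conditions on
    angles and distances used when defining each movement's keyframe.
    """

    kind: str  # "angle" | "distance"
    keypoints: tuple[str, ...]
    min_value: float = -math.inf
    max_value: float = math.inf
    provenance: str = "default"

    def __post_init__(self) -> None:
        if self.kind not in ("angle", "distance"):
            raise ContractError(f"gate kind must be angle|distance, got {self.kind!r}")
        need = 4 if self.kind == "angle" else 2
        if len(self.keypoints) != need:
            raise ContractError(
                f"{self.kind} gate requires {need} keypoints, got {len(self.keypoints)}"
            )
        if self.min_value > self.max_value:
            raise ContractError("gate min_value exceeds max_value")

    def admits(self, s: Skeleton) -> bool:
        if self.kind == "angle":
            value = joint_angle(s, *self.keypoints, min_confidence=None)
        else:
            value = joint_distance(s, *self.keypoints, min_confidence=None)
        return self.min_value <= value <= self.max_value


@dataclass(frozen=True)
class StandardKeyframe:
    """Expert-selected standard pose for one movement.

    ``theta_n`` is always computed from ``skeleton`` at construction time,
    so it can never drift from the stored pose.
    """

    movement_id: str
    skeleton: Skeleton
    selection_gates: tuple[SelectionGate, ...] = field(default_factory=tuple)

    @property
    def theta_n(self) -> PostureDescriptor:
        return posture_theta(self.skeleton)


def posture_theta(s: Skeleton, include_self_term: bool = False) -> PostureDescriptor:
    """Sum of cosines between the right-hip position vector and every other
    keypoint's position vector, both taken from the descriptor-frame origin.

    ``include_self_term`` adds the right hip's own term (identically 1);
    the default excludes it. Including it shifts every frame's Θ by the same
    constant and therefore cannot change any keyframe decision.

    Raises
    ------
    GeometryError
        If any position vector (the right hip's, or any summed keypoint's)
        has norm ≤ 1e-9, making its direction undefined.
    """
    coords = s.coords
    norms = np.linalg.norm(coords, axis=1)
    if norms[RIGHT_HIP] <= 1e-9:
        raise GeometryError(
            "right-hip position vector has zero norm; descriptor undefined"
        )
    bad = np.flatnonzero(norms <= 1e-9)
    if bad.size:
        raise GeometryError(
            f"keypoint position vector(s) with zero norm at indices {bad.tolist()}"
        )
    ref = coords[RIGHT_HIP]
    cosines = (coords @ ref) / (norms * norms[RIGHT_HIP])
    np.clip(cosines, -1.0, 1.0, out=cosines)
    if include_self_term:
        return PostureDescriptor(float(np.sum(cosines)), n_terms=17)
    total = float(np.sum(cosines) - cosines[RIGHT_HIP])
    return PostureDescriptor(total, n_terms=N_DESCRIPTOR_TERMS)


def keyframe_distance(
    theta_k: PostureDescriptor, theta_n: PostureDescriptor
) -> float:
    """One-dimensional Euclidean distance |Θ_K − Θ_N| between descriptors."""
    if theta_k.n_terms != theta_n.n_terms:
        raise ContractError(
            f"descriptor term counts differ: {theta_k.n_terms} vs {theta_n.n_terms}"
        )
    return abs(theta_k.theta - theta_n.theta)


@dataclass(frozen=True)
class KeyframeResult:
    """Outcome of keyframe selection over one sequence."""

    index: int
    distance: float
    theta_trace: tuple[float, ...]  # NaN where a frame's descriptor failed


def extract_keyframe(
    seq: SkeletonSequence, std: StandardKeyframe
) -> KeyframeResult:
    """Select the frame minimizing |Θ_frame − Θ_N|; ties → lowest index.

    Frames whose descriptor cannot be computed are skipped with a warning
    (their trace entry is NaN). When the standard pose carries selection
    gates, only frames passing every gate are candidates; if no frame
    passes, the gates are dropped with a warning rather than failing the
    trial.

    Returns the selected frame's position in the sequence, its distance,
    and the per-frame Θ trace.
    """
    if std.movement_id != seq.movement_id:
        raise ContractError(
            f"movement mismatch: sequence is {seq.movement_id!r}, "
            f"standard keyframe is {std.movement_id!r}"
        )
    theta_n = std.theta_n
    trace: list[float] = []
    candidates: list[tuple[int, float]] = []  # (position, distance)
    gated_out = 0
    for pos, frame in enumerate(seq.frames):
        try:
            theta = posture_theta(frame)
        except GeometryError as exc:
            logger.warning(
                "skipping frame %d of %s/%s: %s",
                frame.frame_index, seq.subject_id, seq.movement_id, exc,
            )
            trace.append(math.nan)
            continue
        trace.append(theta.theta)
        if std.selection_gates and not all(g.admits(frame) for g in std.selection_gates):
            gated_out += 1
            continue
        candidates.append((pos, keyframe_distance(theta, theta_n)))
    if not candidates and gated_out:
        logger.warning(
            "selection gates for %s excluded every frame; falling back to "
            "ungated argmin", seq.movement_id,
        )
        candidates = [
            (pos, abs(t - theta_n.theta))
            for pos, t in enumerate(trace)
            if not math.isnan(t)
        ]
    if not candidates:
        raise ExtractionError(
            f"no frame of {seq.subject_id}/{seq.movement_id} yielded a "
            "posture descriptor"
        )
    best_pos, best_dist = min(candidates, key=lambda pd: (pd[1], pd[0]))
    return KeyframeResult(best_pos, best_dist, tuple(trace))
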