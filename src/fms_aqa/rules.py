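"""Declarative scoring rule base and the indicator-extraction engine.

Each FMS movement carries a list of :class:`Criterion` objects — geometric
checks (joint angle, relative position, joint distance) with a comparator,
a threshold, the score level they gate, and the human-readable scoring
detail and body parts they correspond to. The engine measures every
criterion on a keyframe skeleton (:func:`compute_indicators`), and the
deterministic score mapping (:func:`score_from_indicators`) applies the
hierarchical cascade: all level-3 criteria pass → 3; otherwise all level-2
criteria pass → 2; otherwise 1. Score 0 (pain) requires subject report and
is outside what pose data can carry.

Rule bases are YAML files so that per-movement expert thresholds can be
edited without code changes; entries not taken verbatim from the published
deep-squat criteria are flagged ``provenance: default``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ContractError, InsufficientPoseError
from .errors import ValidationError as RuleValidationError
from .keyframe import SelectionGate, StandardKeyframe
from .skeleton import (
    COCO_KEYPOINTS,
    DEFAULT_MIN_CONFIDENCE,
    DEFAULT_TIE_TOL,
    PositionOrdering,
    Skeleton,
    joint_angle,
    joint_distance,
    relative_position,
)

logger = logging.getLogger(__name__)

MOVEMENT_IDS = tuple(f"m{i:02d}" for i in range(1, 16))

_ORDERING_VALUES = {o.value for o in PositionOrdering}


class Comparator(str, enum.Enum):
    WITHIN = "within"        # measured value ≤ threshold (tolerance around 0)
    BELOW = "below"          # measured value < threshold
    ABOVE = "above"          # measured value > threshold
    ORDERING_EQUALS = "ordering_equals"  # position ordering == threshold


class Criterion(BaseModel):
    """One declarative scoring check tied to a score level.

    ``kind="angle"`` requires four keypoints (two vectors) and a threshold
    in degrees; ``kind="distance"`` two keypoints and a threshold in
    normalized units; ``kind="position"`` two keypoints, an ``axis`` and an
    ordering-valued threshold. ``description`` and ``body_parts`` carry the
    scoring-detail and body-part annotation levels verbatim into reports
    and prompts.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    kind: Literal["angle", "position", "distance"]
    keypoints: tuple[str, ...]
    comparator: Comparator
    threshold: float | str
    level: Literal[2, 3]
    description: str
    body_parts: tuple[str, ...] = ()
    axis: Literal["x", "y"] | None = None
    provenance: str = "default"

    @field_validator("keypoints")
    @classmethod
    def _known_keypoints(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        unknown = [k for k in v if k not in COCO_KEYPOINTS]
        if unknown:
            raise ValueError(f"unknown keypoint name(s): {unknown}")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "Criterion":
        need = 4 if self.kind == "angle" else 2
        if len(self.keypoints) != need:
            raise ValueError(
                f"criterion {self.id!r}: kind={self.kind} requires {need} "
                f"keypoints, got {len(self.keypoints)}"
            )
        if self.kind == "position":
            if self.axis is None:
                raise ValueError(f"criterion {self.id!r}: position requires axis")
            if self.comparator is not Comparator.ORDERING_EQUALS:
                raise ValueError(
                    f"criterion {self.id!r}: position criteria use ordering_equals"
                )
            if self.threshold not in _ORDERING_VALUES:
                raise ValueError(
                    f"criterion {self.id!r}: threshold must be a position "
                    f"ordering, got {self.threshold!r}"
                )
        else:
            if self.comparator is Comparator.ORDERING_EQUALS:
                raise ValueError(
                    f"criterion {self.id!r}: ordering_equals applies to "
                    "position criteria only"
                )
            if not isinstance(self.threshold, (int, float)):
                raise ValueError(
                    f"criterion {self.id!r}: numeric threshold required"
                )
        return self


class MovementSpec(BaseModel):
    """All scoring knowledge for one movement: camera view, the standard
    keyframe pose, optional keyframe selection gates, and the criteria."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    movement_id: str
    name: str
    view: Literal["front", "side"]
    standard: StandardKeyframe
    criteria: tuple[Criterion, ...]

    @field_validator("movement_id")
    @classmethod
    def _known_movement(cls, v: str) -> str:
        if v not in MOVEMENT_IDS:
            raise ValueError(f"movement_id must be one of m01…m15, got {v!r}")
        return v

    @model_validator(mode="after")
    def _non_empty(self) -> "MovementSpec":
        if not self.criteria:
            raise ValueError(f"movement {self.movement_id}: empty criteria list")
        if self.standard.movement_id != self.movement_id:
            raise ValueError(
                f"movement {self.movement_id}: standard keyframe is tagged "
                f"{self.standard.movement_id!r}"
            )
        if not any(c.level == 3 for c in self.criteria):
            raise ValueError(
                f"movement {self.movement_id}: no level-3 criteria"
            )
        return self

    def criteria_at(self, level: int) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if c.level == level)


class RuleBase(BaseModel):
    """Mapping movement_id → :class:`MovementSpec` for all movements present."""

    model_config = ConfigDict(frozen=True)

    movements: dict[str, MovementSpec]

    @model_validator(mode="after")
    def _ids_consistent(self) -> "RuleBase":
        for mid, spec in self.movements.items():
            if spec.movement_id != mid:
                raise ValueError(
                    f"rule-base key {mid!r} does not match spec id "
                    f"{spec.movement_id!r}"
                )
        return self

    def spec(self, movement_id: str) -> MovementSpec:
        try:
            return self.movements[movement_id]
        except KeyError:
            raise ContractError(
                f"movement {movement_id!r} not present in rule base "
                f"(has {sorted(self.movements)})"
            ) from None


@dataclass(frozen=True)
class CriterionResult:
    """Measured outcome of one criterion on one keyframe skeleton."""

    criterion_id: str
    kind: str
    level: int
    measured: float | str | None  # degrees / units / ordering value; None if unmeasurable
    passed: bool | None           # None = indeterminate
    description: str
    body_parts: tuple[str, ...]
    reason: str | None = None     # populated when indeterminate

    @property
    def indeterminate(self) -> bool:
        return self.passed is None


@dataclass(frozen=True)
class IndicatorReport:
    """Complete per-criterion measurement report for one keyframe."""

    movement_id: str
    entries: tuple[CriterionResult, ...]
    keyframe_index: int = 0
    meta: dict = field(default_factory=dict)

    def entry(self, criterion_id: str) -> CriterionResult:
        for e in self.entries:
            if e.criterion_id == criterion_id:
                return e
        raise ContractError(f"no entry for criterion {criterion_id!r}")


# ---------------------------------------------------------------------------
# YAML serialization


def _standard_to_mapping(std: StandardKeyframe) -> dict:
    kps = {
        name: [round(float(x), 9), round(float(y), 9)]
        for name, (x, y) in zip(COCO_KEYPOINTS, std.skeleton.coords)
    }
    out: dict = {"keypoints": kps}
    if std.selection_gates:
        out["selection_gates"] = [
            {
                "kind": g.kind,
                "keypoints": list(g.keypoints),
                "min": None if g.min_value == float("-inf") else g.min_value,
                "max": None if g.max_value == float("inf") else g.max_value,
                "provenance": g.provenance,
            }
            for g in std.selection_gates
        ]
    return out


def _standard_from_mapping(movement_id: str, data: dict, where: str) -> StandardKeyframe:
    kps = data.get("keypoints")
    if not isinstance(kps, dict):
        raise RuleValidationError(f"{where}: standard.keypoints mapping missing")
    missing = [n for n in COCO_KEYPOINTS if n not in kps]
    unknown = [n for n in kps if n not in COCO_KEYPOINTS]
    if missing or unknown:
        raise RuleValidationError(
            f"{where}: standard keypoints missing={missing} unknown={unknown}"
        )
    import numpy as np

    coords = np.array([kps[n] for n in COCO_KEYPOINTS], dtype=float)
    skeleton = Skeleton(
        coords, np.ones(17), frame_index=0, meta={"frame": "normalized"}
    )
    gates = []
    for i, g in enumerate(data.get("selection_gates") or []):
        try:
            gates.append(
                SelectionGate(
                    kind=g["kind"],
                    keypoints=tuple(g["keypoints"]),
                    min_value=float("-inf") if g.get("min") is None else float(g["min"]),
                    max_value=float("inf") if g.get("max") is None else float(g["max"]),
                    provenance=g.get("provenance", "default"),
                )
            )
        except (KeyError, ContractError) as exc:
            raise RuleValidationError(f"{where}: selection_gates[{i}]: {exc}") from exc
    return StandardKeyframe(movement_id, skeleton, tuple(gates))


def rulebase_to_mapping(rb: RuleBase) -> dict:
    movements = {}
    for mid in sorted(rb.movements):
        spec = rb.movements[mid]
        movements[mid] = {
            "name": spec.name,
            "view": spec.view,
            "standard": _standard_to_mapping(spec.standard),
            "criteria": [
                {
                    "id": c.id,
                    "kind": c.kind,
                    "keypoints": list(c.keypoints),
                    **({"axis": c.axis} if c.axis is not None else {}),
                    "comparator": c.comparator.value,
                    "threshold": c.threshold,
                    "level": c.level,
                    "description": c.description,
                    "body_parts": list(c.body_parts),
                    "provenance": c.provenance,
                }
                for c in spec.criteria
            ],
        }
    return {"version": 1, "movements": movements}


def dump_rulebase(rb: RuleBase, path: str | Path | None = None) -> str:
    """Serialize a rule base to canonical YAML (stable key order)."""
    text = yaml.safe_dump(
        rulebase_to_mapping(rb), sort_keys=False, default_flow_style=None
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def rulebase_from_mapping(data: dict) -> RuleBase:
    if not isinstance(data, dict) or "movements" not in data:
        raise RuleValidationError("rule file must contain a 'movements' mapping")
    problems: list[str] = []
    movements: dict[str, MovementSpec] = {}
    for mid, m in data["movements"].items():
        where = f"movements.{mid}"
        try:
            standard = _standard_from_mapping(mid, m.get("standard") or {}, where)
            criteria = tuple(
                Criterion(**c) for c in (m.get("criteria") or [])
            )
            movements[mid] = MovementSpec(
                movement_id=mid,
                name=m.get("name", mid),
                view=m.get("view", "front"),
                standard=standard,
                criteria=criteria,
            )
        except RuleValidationError as exc:
            problems.append(str(exc))
        except Exception as exc:  # pydantic ValidationError and friends
            problems.append(f"{where}: {exc}")
    if problems:
        raise RuleValidationError(
            "rule file validation failed:\n" + "\n".join(problems)
        )
    if not movements:
        raise RuleValidationError("rule file defines no movements")
    return RuleBase(movements=movements)


def load_rulebase(path: str | Path) -> RuleBase:
    """Load and validate a YAML rule base, reporting every offending field."""
    path = Path(path)
    if not path.exists():
        raise RuleValidationError(f"rule file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise RuleValidationError(f"rule file {path} is not valid YAML: {exc}") from exc
    return rulebase_from_mapping(data)


# ---------------------------------------------------------------------------
# Indicator extraction


def evaluate_criterion(
    s: Skeleton,
    c: Criterion,
    tie_tol: float = DEFAULT_TIE_TOL,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> CriterionResult:
    """Measure one criterion on a (normalized) keyframe skeleton.

    A keypoint below the confidence floor yields an *indeterminate* entry
    (passed is None, with the reason recorded) rather than a silent guess.
    """
    try:
        if c.kind == "angle":
            measured: float | str = joint_angle(
                s, *c.keypoints, min_confidence=min_confidence
            )
            value = float(measured)
            if c.comparator is Comparator.WITHIN:
                passed = value <= float(c.threshold)
            elif c.comparator is Comparator.BELOW:
                passed = value < float(c.threshold)
            else:
                passed = value > float(c.threshold)
        elif c.kind == "distance":
            measured = joint_distance(s, *c.keypoints, min_confidence=min_confidence)
            value = float(measured)
            if c.comparator is Comparator.WITHIN:
                passed = value <= float(c.threshold)
            elif c.comparator is Comparator.BELOW:
                passed = value < float(c.threshold)
            else:
                passed = value > float(c.threshold)
        else:  # position
            ordering = relative_position(
                s,
                c.keypoints[0],
                c.keypoints[1],
                axis=c.axis or "y",
                tie_tol=tie_tol,
                min_confidence=min_confidence,
            )
            measured = ordering.value
            passed = ordering.value == c.threshold
    except InsufficientPoseError as exc:
        return CriterionResult(
            criterion_id=c.id,
            kind=c.kind,
            level=c.level,
            measured=None,
            passed=None,
            description=c.description,
            body_parts=c.body_parts,
            reason=str(exc),
        )
    return CriterionResult(
        criterion_id=c.id,
        kind=c.kind,
        level=c.level,
        measured=measured,
        passed=passed,
        description=c.description,
        body_parts=c.body_parts,
    )


def compute_indicators(
    s: Skeleton,
    spec: MovementSpec,
    keyframe_index: int = 0,
    tie_tol: float = DEFAULT_TIE_TOL,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> IndicatorReport:
    """Evaluate every criterion of a movement on a keyframe skeleton.

    The report always contains one entry per criterion, in rule-file order;
    unmeasurable criteria appear as indeterminate entries, never silently
    dropped.
    """
    entries = tuple(
        evaluate_criterion(s, c, tie_tol=tie_tol, min_confidence=min_confidence)
        for c in spec.criteria
    )
    return IndicatorReport(
        movement_id=spec.movement_id,
        entries=entries,
        keyframe_index=keyframe_index,
    )


def score_from_indicators(
    rep: IndicatorReport,
    spec: MovementSpec | None = None,
    allow_indeterminate: bool = False,
) -> int:
    """Map an indicator report to an FMS score in {1, 2, 3}.

    Hierarchical cascade: all level-3 criteria pass → 3; otherwise all
    level-2 criteria pass → 2; otherwise 1. An indeterminate criterion at
    the level currently being decided raises unless ``allow_indeterminate``,
    in which case that level is treated as not achieved (logged). A level
    with no criteria cannot be awarded, so a movement specified only at
    level 3 scores 3 or 1.
    """
    if spec is not None and spec.movement_id != rep.movement_id:
        raise ContractError(
            f"report is for {rep.movement_id!r} but spec is {spec.movement_id!r}"
        )
    if spec is not None and len(rep.entries) != len(spec.criteria):
        raise ContractError(
            f"incomplete report: {len(rep.entries)} entries for "
            f"{len(spec.criteria)} criteria"
        )
    for level, score in ((3, 3), (2, 2)):
        entries = [e for e in rep.entries if e.level == level]
        if not entries:  # a level with no criteria cannot be awarded
            continue
        if any(e.passed is False for e in entries):
            continue
        indeterminate = [e for e in entries if e.indeterminate]
        if indeterminate:
            ids = [e.criterion_id for e in indeterminate]
            if not allow_indeterminate:
                raise InsufficientPoseError(
                    f"criteria {ids} are indeterminate at the deciding "
                    f"level {level} for {rep.movement_id}"
                )
            logger.warning(
                "indeterminate criteria %s at level %d for %s; degrading",
                ids, level, rep.movement_id,
            )
            continue
        return score
    return 1
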