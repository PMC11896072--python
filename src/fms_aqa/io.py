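"""File formats and run configuration.

Keypoint files use the COCO keypoint-array dialect emitted by common pose
estimators: per frame, 17 ``[x, y, confidence]`` triples in canonical COCO
order, with coordinates in raw image pixels (y-down). The y-flip to the
internal y-up convention and torso-length normalization happen at read
time, so files on disk stay tool-compatible. Every artifact written here
is re-readable by the module that consumes it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .assess import Assessment
from .errors import ValidationError
from .keyframe import KeyframeResult
from .skeleton import Skeleton, SkeletonSequence, normalize_skeleton
from .synthetic import Annotation

DEFAULT_IMAGE_HEIGHT = 480.0
DEFAULT_PIXEL_SCALE = 200.0  # pixels per torso unit when writing


# ---------------------------------------------------------------------------
# Keypoint sequences


def read_keypoint_sequence(path: str | Path) -> SkeletonSequence:
    """Read a keypoint JSON file into a normalized, y-up sequence.

    Validates that every frame carries exactly 17 ``[x, y, confidence]``
    triples; violations name the offending frame. Provenance (source path,
    frame count, image height) is recorded in the sequence metadata.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot read keypoint file {path}: {exc}") from exc
    for key in ("movement_id", "frames"):
        if key not in data:
            raise ValidationError(f"{path}: missing required field {key!r}")
    image_height = float(data.get("image_height", DEFAULT_IMAGE_HEIGHT))
    frames = []
    for fi, frame in enumerate(data["frames"]):
        kps = frame.get("keypoints")
        if not isinstance(kps, list) or len(kps) != 17:
            raise ValidationError(
                f"{path}: frame {fi} has {0 if not isinstance(kps, list) else len(kps)}"
                " keypoint triples, expected 17"
            )
        if any(not isinstance(t, list) or len(t) != 3 for t in kps):
            raise ValidationError(
                f"{path}: frame {fi} contains a malformed [x, y, confidence] triple"
            )
        arr = np.asarray(kps, dtype=float)
        raw = Skeleton(
            arr[:, :2],
            np.clip(arr[:, 2], 0.0, 1.0),
            frame_index=int(frame.get("frame_index", fi)),
            meta={"frame": "image"},
        )
        frames.append(normalize_skeleton(raw, image_height))
    return SkeletonSequence(
        frames=tuple(frames),
        movement_id=str(data["movement_id"]),
        subject_id=str(data.get("subject_id", "anonymous")),
        meta={
            "source": str(path),
            "n_frames": len(frames),
            "image_height": image_height,
        },
    )


def write_keypoint_sequence(
    seq: SkeletonSequence,
    path: str | Path,
    image_height: float = DEFAULT_IMAGE_HEIGHT,
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
) -> Path:
    """Write a sequence as COCO-dialect keypoint JSON (pixels, y-down).

    Normalized (y-up) coordinates are mapped to pixels with
    ``x_px = x · pixel_scale`` and ``y_px = image_height − y · pixel_scale``,
    which :func:`read_keypoint_sequence` inverts exactly up to the torso
    rescaling.
    """
    path = Path(path)
    frames = []
    for s in seq.frames:
        coords = s.coords
        if s.is_normalized():
            xs = coords[:, 0] * pixel_scale
            ys = image_height - coords[:, 1] * pixel_scale
        else:  # already image-frame pixels
            xs, ys = coords[:, 0], coords[:, 1]
        frames.append(
            {
                "frame_index": s.frame_index,
                "keypoints": [
                    [float(x), float(y), float(c)]
                    for x, y, c in zip(xs, ys, s.confidence)
                ],
            }
        )
    payload = {
        "movement_id": seq.movement_id,
        "subject_id": seq.subject_id,
        "image_height": image_height,
        "frames": frames,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))
    return path


# ---------------------------------------------------------------------------
# Annotations, keyframes, assessments


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps([a.model_dump() for a in annotations], indent=1)
    )
    return path


def read_annotations(path: str | Path) -> list[Annotation]:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot read annotations {path}: {exc}") from exc
    try:
        return [Annotation(**rec) for rec in data]
    except Exception as exc:
        raise ValidationError(f"invalid annotation record in {path}: {exc}") from exc


def keyframe_to_json(result: KeyframeResult) -> dict:
    return {
        "index": result.index,
        "distance": result.distance,
        "theta_trace": [None if t != t else t for t in result.theta_trace],
    }


def assessment_to_json(a: Assessment) -> dict:
    """Audit-complete serialization: score plus every intermediate."""
    return {
        "subject_id": a.subject_id,
        "movement_id": a.movement_id,
        "score": a.result.score,
        "rationale": a.result.rationale,
        "per_criterion_feedback": list(a.result.per_criterion_feedback),
        "backend_id": a.result.backend_id,
        "keyframe": keyframe_to_json(a.keyframe),
        "prompt_hash": a.prompt.prompt_hash,
        "render_version": a.prompt.render_version,
        "report": [
            {
                "criterion_id": e.criterion_id,
                "kind": e.kind,
                "level": e.level,
                "measured": e.measured,
                "passed": e.passed,
                "description": e.description,
                "body_parts": list(e.body_parts),
                **({"reason": e.reason} if e.reason else {}),
            }
            for e in a.report.entries
        ],
    }


def write_assessments(assessments: Iterable[Assessment], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps([assessment_to_json(a) for a in assessments], indent=1)
    )
    return path


def read_assessments(path: str | Path) -> list[dict]:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot read assessments {path}: {exc}") from exc
    required = {"subject_id", "movement_id", "score"}
    for i, rec in enumerate(data):
        if not required <= set(rec):
            raise ValidationError(
                f"{path}: assessment record {i} lacks {sorted(required - set(rec))}"
            )
    return data


# ---------------------------------------------------------------------------
# Run configuration


class RunConfig(BaseModel):
    """Pipeline configuration; CLI flags override file values which
    override these defaults."""

    model_config = ConfigDict(frozen=True)

    rulebase: str | None = None          # path to a YAML rule base; None = shipped defaults
    template_dir: str | None = None      # None = packaged templates
    backend: str = "mock"
    confidence_threshold: float = 0.3
    tie_tol: float = 0.01
    allow_indeterminate: bool = False
    seed: int = 0
    out_dir: str = "out"

    def validated(self) -> "RunConfig":
        if self.tie_tol < 0 or not (0 <= self.confidence_threshold <= 1):
            raise ValidationError(
                "tie_tol must be ≥ 0 and confidence_threshold within [0, 1]"
            )
        for label, p in (("rulebase", self.rulebase), ("template_dir", self.template_dir)):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{label} path does not exist: {p}")
        return self

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build a config from an optional YAML file plus keyword overrides
        (``None`` overrides are ignored)."""
        data: dict = {}
        if path is not None:
            p = Path(path)
            if not p.exists():
                raise ValidationError(f"config file not found: {p}")
            loaded = yaml.safe_load(p.read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValidationError(f"config file {p} must be a mapping")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**data).validated()
        except ValidationError:
            raise
        except Exception as exc:
            raise ValidationError(f"invalid configuration: {exc}") from exc
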