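"""Structured exception hierarchy.

Every pipeline stage raises a subclass of :class:`FmsError` so callers (and
the CLI) can map failures to categories without string matching.
"""

from __future__ import annotations


class FmsError(Exception):
    """Base class for all package errors."""

    category = "error"


class GeometryError(FmsError):
    """A geometric computation is degenerate (zero-length vector, zero torso)."""

    category = "geometry"


class InsufficientPoseError(FmsError):
    """A required keypoint is missing or below the confidence threshold."""

    category = "insufficient_pose"

    def __init__(self, message: str, keypoint: str | None = None):
        super().__init__(message)
        self.keypoint = keypoint


class ContractError(FmsError):
    """A caller violated an interface precondition (mismatched ids, empty input)."""

    category = "contract"


class ValidationError(FmsError):
    """A declarative file (rule base, config, keypoint JSON) failed validation."""

    category = "validation"


class ExtractionError(FmsError):
    """Keyframe extraction could not produce a result (all frames degenerate)."""

    category = "extraction"


class RenderError(FmsError):
    """A prompt template referenced a field the report does not provide."""

    category = "render"


class ParseError(FmsError):
    """An LLM response carried no extractable score."""

    category = "parse"

    def __init__(self, message: str, raw: str = ""):
        super().__init__(message)
        self.raw = raw


class BackendError(FmsError):
    """An assessment backend failed (transport, timeout, refusal)."""

    category = "backend"


class ConstructionError(FmsError):
    """A synthetic pose recipe is geometrically unsatisfiable or out of range."""

    category = "construction"
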