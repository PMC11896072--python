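"""Prompt generation and score assessment.

The pipeline turns an indicator report into a natural-language prompt that
embeds the expert scoring rules and the measured indicator values, sends it
to a pluggable assessment backend (the contract ``L: prompt → text``), and
parses the response into a score in {1, 2, 3} plus a rationale. The shipped
:class:`MockBackend` is deterministic: it applies the rule cascade to the
report embedded in the prompt and renders a templated rationale, so the
whole pipeline is testable offline; adapters for hosted language models
implement the same one-method contract.

Every assessment keeps its intermediates (keyframe index, report, prompt,
raw response) — interpretability of the score is the point, so no score is
produced without its provenance.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Protocol, runtime_checkable

from .errors import FmsError, ParseError, RenderError
from .keyframe import KeyframeResult, extract_keyframe
from .rules import (
    CriterionResult,
    IndicatorReport,
    MovementSpec,
    RuleBase,
    compute_indicators,
    score_from_indicators,
)
from .skeleton import DEFAULT_MIN_CONFIDENCE, DEFAULT_TIE_TOL, SkeletonSequence

_SYSTEM_TEXT = (
    "You are an experienced Functional Movement Screen (FMS) assessor. "
    "You grade one movement trial from measured skeletal indicators, "
    "strictly following the expert scoring rules you are given. Respond "
    "with a line 'Score: N' (N in 1-3) followed by a rationale that names "
    "each unmet criterion and suggests an improvement."
)


def format_measured(entry: CriterionResult) -> str:
    """Human-readable measured value: angles to 1 decimal place in degrees,
    distances to 3 decimals, orderings as words."""
    if entry.measured is None:
        return f"unmeasurable ({entry.reason})"
    if entry.kind == "angle":
        return f"{float(entry.measured):.1f} degrees"
    if entry.kind == "distance":
        return f"{float(entry.measured):.3f} torso units"
    return str(entry.measured).replace("_", " ")


def _status(entry: CriterionResult) -> str:
    if entry.indeterminate:
        return "indeterminate"
    return "satisfied" if entry.passed else "violated"


def _indicator_lines(rep: IndicatorReport) -> str:
    lines = []
    for e in rep.entries:
        lines.append(
            f"- [level {e.level}] {e.description} "
            f"measured: {format_measured(e)}; status: {_status(e)}; "
            f"body parts: {', '.join(e.body_parts) if e.body_parts else 'n/a'}"
        )
    return "\n".join(lines)


def _rule_lines(spec: MovementSpec) -> str:
    lines = []
    for level in (3, 2):
        crits = spec.criteria_at(level)
        if not crits:
            continue
        lines.append(f"Score {level} requires all of:")
        for c in crits:
            if c.kind == "position":
                req = f"{c.keypoints[0]} must be {str(c.threshold).replace('_', ' ')} {c.keypoints[1]} (axis {c.axis})"
            elif c.kind == "angle":
                op = {"within": "at most", "below": "less than", "above": "greater than"}[c.comparator.value]
                req = f"angle({', '.join(c.keypoints)}) {op} {float(c.threshold):.1f} degrees"
            else:
                op = {"within": "at most", "below": "less than", "above": "greater than"}[c.comparator.value]
                req = f"distance({', '.join(c.keypoints)}) {op} {float(c.threshold):.3f} torso units"
            lines.append(f"  - {c.description} ({req})")
    lines.append("A trial meeting neither pattern scores 1.")
    return "\n".join(lines)


@dataclass(frozen=True)
class Prompt:
    """A rendered assessment prompt plus the report it was rendered from.

    ``user_text`` contains every measured indicator value of the source
    report (angles to 1 decimal place); ``report`` and ``spec`` ride along
    for the mock backend and for the audit trail, never for re-rendering.
    """

    movement_id: str
    system_text: str
    user_text: str
    render_version: str
    report: IndicatorReport = field(repr=False, compare=False, default=None)  # type: ignore[assignment]
    spec: MovementSpec = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    @property
    def prompt_hash(self) -> str:
        digest = hashlib.sha256(
            (self.system_text + "\n\x00\n" + self.user_text).encode()
        ).hexdigest()
        return digest[:16]


def _load_template(movement_id: str, template_dir: str | Path | None) -> tuple[str, str]:
    """Return (template_text, template_name); per-movement file wins over
    the default template."""
    if template_dir is not None:
        base = Path(template_dir)
        for name in (f"{movement_id}.txt", "default.txt"):
            p = base / name
            if p.exists():
                return p.read_text(), name
        raise RenderError(f"no template for {movement_id} in {base}")
    pkg = resources.files("fms_aqa.templates")
    for name in (f"{movement_id}.txt", "default.txt"):
        p = pkg / name
        if p.is_file():
            return p.read_text(), name
    raise RenderError(f"no packaged template for {movement_id}")


def build_prompt(
    rep: IndicatorReport,
    spec: MovementSpec,
    template_dir: str | Path | None = None,
) -> Prompt:
    """Render the assessment prompt for one indicator report.

    Rendering is deterministic: identical inputs yield a byte-identical
    prompt. Besides the aggregate fields (``rules_text``,
    ``indicators_text``), templates may reference any single measurement as
    ``measured_<criterion_id>``; a placeholder with no matching report
    field raises :class:`RenderError` naming it.
    """
    if rep.movement_id != spec.movement_id:
        raise RenderError(
            f"report is for {rep.movement_id!r} but spec is {spec.movement_id!r}"
        )
    template, template_name = _load_template(spec.movement_id, template_dir)
    fields: dict[str, str] = {
        "movement_id": spec.movement_id,
        "movement_name": spec.name,
        "view": spec.view,
        "keyframe_index": str(rep.keyframe_index),
        "rules_text": _rule_lines(spec),
        "indicators_text": _indicator_lines(rep),
    }
    for e in rep.entries:
        fields[f"measured_{e.criterion_id}"] = format_measured(e)
    try:
        user_text = template.format_map(fields)
    except KeyError as exc:
        raise RenderError(
            f"template {template_name} references unknown placeholder "
            f"{exc.args[0]!r}; report provides {sorted(fields)}"
        ) from exc
    version = f"{template_name}@{hashlib.sha256(template.encode()).hexdigest()[:8]}"
    return Prompt(
        movement_id=spec.movement_id,
        system_text=_SYSTEM_TEXT,
        user_text=user_text,
        render_version=version,
        report=rep,
        spec=spec,
    )


@runtime_checkable
class AssessmentBackend(Protocol):
    """The backend contract L: a rendered prompt in, raw text out.

    Real adapters must use deterministic decoding settings where the
    service allows; all shipped tests run against :class:`MockBackend`.
    """

    backend_id: str

    def generate(self, prompt: Prompt) -> str: ...


class MockBackend:
    """Deterministic stand-in for a language model.

    Computes the score by applying the rule cascade to the report embedded
    in the prompt and renders a templated rationale naming every violated
    criterion's description verbatim. Identical prompts yield identical
    output.
    """

    backend_id = "mock"

    def __init__(self, allow_indeterminate: bool = False):
        self.allow_indeterminate = allow_indeterminate

    def generate(self, prompt: Prompt) -> str:
        rep = prompt.report
        if rep is None:
            raise FmsError("mock backend requires a prompt with an embedded report")
        score = score_from_indicators(
            rep, prompt.spec, allow_indeterminate=self.allow_indeterminate
        )
        failed = [e for e in rep.entries if e.passed is False]
        lines = [f"Score: {score}"]
        if failed:
            lines.append("The following criteria were not met:")
            for e in failed:
                lines.append(
                    f"- {e.description} (measured {format_measured(e)}; "
                    f"focus on: {', '.join(e.body_parts) if e.body_parts else 'form'})"
                )
        else:
            lines.append("All evaluated criteria were met at the awarded level.")
        indet = [e for e in rep.entries if e.indeterminate]
        for e in indet:
            lines.append(f"- Could not verify: {e.description} ({e.reason})")
        return "\n".join(lines)


@dataclass(frozen=True)
class AssessmentResult:
    """Parsed backend output: a score in {1, 2, 3} with its rationale."""

    score: int
    rationale: str
    per_criterion_feedback: tuple[str, ...] = ()
    backend_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3):
            raise ParseError(f"score {self.score} outside {{1, 2, 3}}")


_SCORE_PATTERNS = (
    re.compile(r"\bscore\s*(?:is|:|=)\s*([123])\b", re.IGNORECASE),
    re.compile(r"^\s*([123])\b"),
)


def parse_llm_response(raw: str, backend_id: str = "unknown") -> AssessmentResult:
    """Extract the first tagged score in {1, 2, 3}; the rest is rationale.

    Tolerant of the common phrasings ``Score: N``, ``the score is N`` and a
    leading bare ``N``. Raises :class:`ParseError` (carrying the raw text)
    when no score can be extracted.
    """
    for pattern in _SCORE_PATTERNS:
        m = pattern.search(raw)
        if m:
            score = int(m.group(1))
            rationale = (raw[: m.start()] + raw[m.end() :]).strip(" :\n")
            return AssessmentResult(
                score=score, rationale=rationale, backend_id=backend_id
            )
    raise ParseError("no score in {1, 2, 3} found in backend response", raw=raw)


@dataclass(frozen=True)
class Assessment:
    """Full audited outcome of one trial: every intermediate is retained."""

    movement_id: str
    subject_id: str
    keyframe: KeyframeResult
    report: IndicatorReport
    prompt: Prompt
    raw_response: str
    result: AssessmentResult


def _staged(stage: str, exc: FmsError) -> FmsError:
    exc.add_note(f"pipeline stage: {stage}")
    return exc


def assess(
    seq: SkeletonSequence,
    rulebase: RuleBase,
    backend: AssessmentBackend | None = None,
    template_dir: str | Path | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> Assessment:
    """Run the full pipeline on one sequence.

    Composes keyframe extraction → indicator computation → prompt rendering
    → backend → response parsing, returning all intermediates for audit.
    Stage failures propagate with the stage name attached as an exception
    note.
    """
    if backend is None:
        backend = MockBackend()
    spec = rulebase.spec(seq.movement_id)
    try:
        kf = extract_keyframe(seq, spec.standard)
    except FmsError as exc:
        raise _staged("extract_keyframe", exc)
    try:
        report = compute_indicators(
            seq.frames[kf.index],
            spec,
            keyframe_index=kf.index,
            tie_tol=tie_tol,
            min_confidence=min_confidence,
        )
    except FmsError as exc:
        raise _staged("compute_indicators", exc)
    try:
        prompt = build_prompt(report, spec, template_dir=template_dir)
    except FmsError as exc:
        raise _staged("build_prompt", exc)
    try:
        raw = backend.generate(prompt)
    except FmsError as exc:
        raise _staged("backend", exc)
    try:
        result = parse_llm_response(raw, backend_id=backend.backend_id)
    except FmsError as exc:
        raise _staged("parse_llm_response", exc)
    if not result.per_criterion_feedback:
        feedback = tuple(
            f"{e.criterion_id}: {_status(e)} ({format_measured(e)})"
            for e in report.entries
        )
        result = AssessmentResult(
            score=result.score,
            rationale=result.rationale,
            per_criterion_feedback=feedback,
            backend_id=result.backend_id,
        )
    return Assessment(
        movement_id=seq.movement_id,
        subject_id=seq.subject_id,
        keyframe=kf,
        report=report,
        prompt=prompt,
        raw_response=raw,
        result=result,
    )
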