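"""Parsing and validation of ADL scripts.

An ADL script is a plain-text description of how one user lives in a
dense-sensing smart environment.  It carries four ordered sections:

``DAYS``
    the number of days to simulate (a positive integer);
``ACTIVITIES``
    one block per activity: a header ``<Name> <n_patterns>`` followed by
    ``n_patterns`` sensor-activation patterns, each an occurrence
    probability and a sequence of ``sensor@lapse`` tokens where the lapse
    is the time in seconds after the *previous* activation (the first
    activation's lapse must be 0);
``BEHAVIOURS``
    one block per behaviour model (a kind of day): a header ``Prob <p>``
    followed by sequence lines ``S HH:MM - HH:MM Act@0 Act@lapse ...``
    (always performed, first activity starting uniformly inside the time
    slot, later activities starting ``lapse`` seconds after the previous
    activity's end) and alteration lines ``A <p> HH:MM - HH:MM <Act>``
    (the activity is performed in the slot only with probability ``p``);
``NOISE``
    positive sensor noise: ``<sensor> <p>`` lines giving each sensor an
    independent per-hour probability of a spurious activation.

``#`` starts a comment, blank lines are ignored, and the en dash "–" is
accepted interchangeably with "-" in time slots.  The full grammar is
documented in ``docs/adl_script_grammar.md``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

__all__ = [
    "ScriptSyntaxError",
    "SensorActivationStep",
    "SensorActivationPattern",
    "ActivityDefinition",
    "TimeSlot",
    "SequenceSpec",
    "AlterationSpec",
    "BehaviourModel",
    "ADLScript",
    "parse_adl_script",
    "serialize_adl_script",
    "validate_script",
    "days_per_week_probability",
]

#: label reserved for noise events in the output dataset
NOISE_LABEL = "None"

#: tolerance for probability groups that must sum to one
PROB_SUM_TOL = 1e-6


class ScriptSyntaxError(ValueError):
    """Raised for any unresolvable construct in an ADL script."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class SensorActivationStep:
    """One sensor activation inside a pattern.

    ``lapse_s`` is the delay in seconds relative to the previous step; the
    first step of a pattern always has ``lapse_s == 0``.
    """

    sensor_name: str
    lapse_s: int

    def __post_init__(self) -> None:
        if self.lapse_s < 0:
            raise ValueError(f"negative lapse {self.lapse_s} for {self.sensor_name}")


@dataclass(frozen=True)
class SensorActivationPattern:
    """One way of performing an activity: a probability and ordered steps."""

    probability: float
    steps: tuple[SensorActivationStep, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"pattern probability {self.probability} outside [0, 1]")
        if not self.steps:
            raise ValueError("pattern has no steps")
        if self.steps[0].lapse_s != 0:
            raise ValueError("first sensor activation's lapse must be zero")

    @property
    def duration_s(self) -> int:
        """Nominal duration implied by the lapse sum (before randomisation)."""
        return sum(s.lapse_s for s in self.steps)


@dataclass(frozen=True)
class ActivityDefinition:
    name: str
    patterns: tuple[SensorActivationPattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"activity {self.name} has no patterns")


_TIME_RE = re.compile(r"^(\d{1,2}):(\d{2})(?::(\d{2}))?$")


def _parse_clock(token: str) -> int:
    """HH:MM or HH:MM:SS -> seconds since midnight (24:00 allowed as end)."""
    m = _TIME_RE.match(token)
    if not m:
        raise ValueError(f"malformed time {token!r} (expected HH:MM)")
    h, mi, s = int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)
    if h > 24 or mi > 59 or s > 59 or (h == 24 and (mi or s)):
        raise ValueError(f"malformed time {token!r}")
    return h * 3600 + mi * 60 + s


def _format_clock(seconds: int) -> str:
    h, rem = divmod(seconds, 3600)
    mi, s = divmod(rem, 60)
    return f"{h:02d}:{mi:02d}" if s == 0 else f"{h:02d}:{mi:02d}:{s:02d}"


@dataclass(frozen=True)
class TimeSlot:
    """Half-open window of the day, in seconds since midnight."""

    start_s: int
    end_s: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s <= 86400:
            raise ValueError(
                f"malformed time slot [{self.start_s}, {self.end_s}] "
                "(need 0 <= start < end <= 86400)"
            )

    def __str__(self) -> str:
        return f"{_format_clock(self.start_s)} - {_format_clock(self.end_s)}"


@dataclass(frozen=True)
class SequenceSpec:
    """A time-slotted list of activities that is always performed.

    ``items`` are ``(activity_name, lapse_s)`` pairs; the first lapse is 0
    and later lapses are measured from the previous activity's end.
    """

    slot: TimeSlot
    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.items:
            if self.items[0][1] != 0:
                raise ValueError("first activity of a sequence must have lapse 0")
            if any(lapse < 0 for _, lapse in self.items):
                raise ValueError("negative lapse in sequence")


@dataclass(frozen=True)
class AlterationSpec:
    """An activity performed in a slot only with a given probability."""

    probability: float
    slot: TimeSlot
    activity_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"alteration probability {self.probability} outside [0, 1]")


BehaviourElement = Union[SequenceSpec, AlterationSpec]


@dataclass(frozen=True)
class BehaviourModel:
    """A kind of day: occurrence probability plus ordered sequences/alterations."""

    probability: float
    elements: tuple[BehaviourElement, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"behaviour probability {self.probability} outside [0, 1]")


@dataclass
class ADLScript:
    """Fully parsed user model: days, activities, behaviours, positive noise."""

    days: int
    activities: dict[str, ActivityDefinition]
    behaviour_models: list[BehaviourModel]
    positive_noise: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError(f"days must be >= 1, got {self.days}")
        for name, p in self.positive_noise.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"noise probability {p} for {name} outside [0, 1]")


def days_per_week_probability(days_per_week: int) -> float:
    """Occurrence probability of a day model happening ``days_per_week`` days a week.

    A weekend-only day model, for instance, has probability 2/7 ≈ 0.29.
    """
    if not 0 <= days_per_week <= 7:
        raise ValueError("days_per_week must be in 0..7")
    return days_per_week / 7.0


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------

_SECTIONS = ("DAYS", "ACTIVITIES", "BEHAVIOURS", "NOISE")
_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _strip(line: str) -> str:
    return line.split("#", 1)[0].strip()


def _numbered_lines(text: str):
    for i, raw in enumerate(text.splitlines(), start=1):
        content = _strip(raw)
        if content:
            yield i, content


def _parse_prob(token: str, line_no: int, what: str) -> float:
    try:
        p = float(token)
    except ValueError:
        raise ScriptSyntaxError(f"{what}: expected a probability, got {token!r}", line_no)
    if not 0.0 <= p <= 1.0:
        raise ScriptSyntaxError(f"{what}: probability {p} outside [0, 1]", line_no)
    return p


def _parse_at_token(token: str, line_no: int) -> tuple[str, int]:
    """``name@lapse`` -> (name, lapse_seconds)."""
    if "@" not in token:
        raise ScriptSyntaxError(f"expected name@lapse, got {token!r}", line_no)
    name, _, lapse_txt = token.partition("@")
    if not _IDENT_RE.match(name):
        raise ScriptSyntaxError(f"invalid identifier {name!r}", line_no)
    try:
        lapse = int(lapse_txt)
    except ValueError:
        raise ScriptSyntaxError(f"invalid lapse {lapse_txt!r} in {token!r}", line_no)
    if lapse < 0:
        raise ScriptSyntaxError(f"negative lapse {lapse} in {token!r}", line_no)
    return name, lapse


def _parse_slot(tokens: list[str], line_no: int) -> tuple[TimeSlot, list[str]]:
    """Consume a time slot from the front of ``tokens``; return (slot, rest).

    Accepts ``HH:MM - HH:MM`` (dash as its own token, "-" or "–") as well
    as the compact ``HH:MM-HH:MM``.
    """
    tokens = [t.replace("–", "-") for t in tokens]
    if len(tokens) >= 3 and tokens[1] == "-":
        start_txt, end_txt, rest = tokens[0], tokens[2], tokens[3:]
    elif tokens and tokens[0].count("-") == 1 and ":" in tokens[0]:
        start_txt, _, end_txt = tokens[0].partition("-")
        rest = tokens[1:]
    else:
        raise ScriptSyntaxError("malformed time slot (expected HH:MM - HH:MM)", line_no)
    try:
        slot = TimeSlot(_parse_clock(start_txt), _parse_clock(end_txt))
    except ValueError as exc:
        raise ScriptSyntaxError(str(exc), line_no)
    return slot, rest


def parse_adl_script(text: str) -> ADLScript:
    """Parse ADL-script source into an :class:`ADLScript`.

    Any unresolvable construct raises :class:`ScriptSyntaxError` carrying
    the offending line number; nothing is silently skipped.
    """
    if not text.strip():
        raise ScriptSyntaxError("empty script")

    lines = list(_numbered_lines(text))
    pos = 0

    def peek():
        return lines[pos] if pos < len(lines) else (None, None)

    def expect_section(name: str) -> None:
        nonlocal pos
        line_no, content = peek()
        if content != name:
            raise ScriptSyntaxError(f"expected section header {name!r}", line_no)
        pos += 1

    # DAYS
    expect_section("DAYS")
    line_no, content = peek()
    if content is None:
        raise ScriptSyntaxError("missing day count after DAYS")
    try:
        days = int(content)
    except ValueError:
        raise ScriptSyntaxError(f"expected an integer day count, got {content!r}", line_no)
    if days < 1:
        raise ScriptSyntaxError(f"days must be >= 1, got {days}", line_no)
    pos += 1

    # ACTIVITIES
    expect_section("ACTIVITIES")
    activities: dict[str, ActivityDefinition] = {}
    while True:
        line_no, content = peek()
        if content is None or content in _SECTIONS:
            break
        tokens = content.split()
        if len(tokens) != 2 or not _IDENT_RE.match(tokens[0]):
            raise ScriptSyntaxError(
                f"expected activity header '<Name> <n_patterns>', got {content!r}", line_no
            )
        name = tokens[0]
        if name in activities:
            raise ScriptSyntaxError(f"duplicate activity {name!r}", line_no)
        if name == NOISE_LABEL:
            raise ScriptSyntaxError(f"{NOISE_LABEL!r} is reserved for noise events", line_no)
        try:
            n_patterns = int(tokens[1])
        except ValueError:
            raise ScriptSyntaxError(f"invalid pattern count {tokens[1]!r}", line_no)
        if n_patterns < 1:
            raise ScriptSyntaxError("an activity needs at least one pattern", line_no)
        pos += 1
        patterns = []
        for _ in range(n_patterns):
            line_no, content = peek()
            if content is None or content in _SECTIONS:
                raise ScriptSyntaxError(
                    f"activity {name!r} declares {n_patterns} patterns but fewer follow",
                    line_no,
                )
            tokens = content.split()
            if len(tokens) < 2:
                raise ScriptSyntaxError("pattern needs a probability and steps", line_no)
            prob = _parse_prob(tokens[0], line_no, f"pattern of {name}")
            steps = tuple(
                SensorActivationStep(*_parse_at_token(t, line_no)) for t in tokens[1:]
            )
            if steps[0].lapse_s != 0:
                raise ScriptSyntaxError(
                    "first sensor activation's lapse must be zero "
                    f"(got {steps[0].sensor_name}@{steps[0].lapse_s})",
                    line_no,
                )
            patterns.append(SensorActivationPattern(prob, steps))
            pos += 1
        activities[name] = ActivityDefinition(name, tuple(patterns))

    # BEHAVIOURS
    expect_section("BEHAVIOURS")
    behaviour_models: list[BehaviourModel] = []
    while True:
        line_no, content = peek()
        if content is None or content in _SECTIONS:
            break
        tokens = content.split()
        if tokens[0] != "Prob" or len(tokens) != 2:
            raise ScriptSyntaxError(
                f"expected behaviour header 'Prob <p>', got {content!r}", line_no
            )
        model_prob = _parse_prob(tokens[1], line_no, "behaviour model")
        pos += 1
        elements: list[BehaviourElement] = []
        while True:
            line_no, content = peek()
            if content is None or content in _SECTIONS or content.startswith("Prob"):
                break
            tokens = content.split()
            kind, rest = tokens[0], tokens[1:]
            try:
                if kind == "S":
                    slot, rest = _parse_slot(rest, line_no)
                    items = tuple(_parse_at_token(t, line_no) for t in rest)
                    if not items:
                        raise ScriptSyntaxError("sequence lists no activities", line_no)
                    if items[0][1] != 0:
                        raise ScriptSyntaxError(
                            "first activity of a sequence must have lapse 0", line_no
                        )
                    elements.append(SequenceSpec(slot, items))
                elif kind == "A":
                    if not rest:
                        raise ScriptSyntaxError("alteration needs a probability", line_no)
                    p = _parse_prob(rest[0], line_no, "alteration")
                    slot, rest = _parse_slot(rest[1:], line_no)
                    if len(rest) != 1 or not _IDENT_RE.match(rest[0]):
                        raise ScriptSyntaxError(
                            "alteration needs exactly one activity name", line_no
                        )
                    elements.append(AlterationSpec(p, slot, rest[0]))
                else:
                    raise ScriptSyntaxError(
                        f"expected an 'S' or 'A' line, got {content!r}", line_no
                    )
            except ValueError as exc:
                if isinstance(exc, ScriptSyntaxError):
                    raise
                raise ScriptSyntaxError(str(exc), line_no)
            pos += 1
        behaviour_models.append(BehaviourModel(model_prob, tuple(elements)))

    # NOISE
    expect_section("NOISE")
    positive_noise: dict[str, float] = {}
    while True:
        line_no, content = peek()
        if content is None:
            break
        tokens = content.split()
        if len(tokens) != 2 or not _IDENT_RE.match(tokens[0]):
            raise ScriptSyntaxError(
                f"expected noise line '<sensor> <p>', got {content!r}", line_no
            )
        if tokens[0] in positive_noise:
            raise ScriptSyntaxError(f"duplicate noise sensor {tokens[0]!r}", line_no)
        positive_noise[tokens[0]] = _parse_prob(tokens[1], line_no, f"noise {tokens[0]}")
        pos += 1

    return ADLScript(days, activities, behaviour_models, positive_noise)


def serialize_adl_script(script: ADLScript) -> str:
    """Render a script back to source text; re-parsing yields an equal script."""
    out = ["DAYS", str(script.days), "", "ACTIVITIES"]
    for act in script.activities.values():
        out.append(f"{act.name} {len(act.patterns)}")
        for pat in act.patterns:
            steps = " ".join(f"{s.sensor_name}@{s.lapse_s}" for s in pat.steps)
            out.append(f"{pat.probability!r} {steps}")
    out += ["", "BEHAVIOURS"]
    for model in script.behaviour_models:
        out.append(f"Prob {model.probability!r}")
        for el in model.elements:
            if isinstance(el, SequenceSpec):
                items = " ".join(f"{name}@{lapse}" for name, lapse in el.items)
                out.append(f"S {el.slot} {items}")
            else:
                out.append(f"A {el.probability!r} {el.slot} {el.activity_name}")
    out += ["", "NOISE"]
    for name, p in script.positive_noise.items():
        out.append(f"{name} {p!r}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# validation against context knowledge
# ---------------------------------------------------------------------------


def validate_script(script: ADLScript, ctx) -> list[str]:
    """Cross-check a parsed script against context knowledge.

    Returns a list of human-readable findings; an empty list means the pair
    is coherent.  Callers treat any finding as fatal.  Checks: every sensor
    named in a pattern or the noise section exists in the context, every
    activity referenced by a behaviour element is defined, and each
    probability group (per-activity patterns; behaviour models) sums to one
    within ``PROB_SUM_TOL``.
    """
    findings: list[str] = []
    known_sensors = {s.name for s in ctx.sensors}

    for act in script.activities.values():
        total = sum(p.probability for p in act.patterns)
        if abs(total - 1.0) > PROB_SUM_TOL:
            findings.append(
                f"activity {act.name!r}: pattern probabilities sum to {total:g}, not 1"
            )
        for pat in act.patterns:
            for step in pat.steps:
                if step.sensor_name not in known_sensors:
                    findings.append(
                        f"activity {act.name!r} uses sensor {step.sensor_name!r} "
                        "not present in the context knowledge"
                    )

    if script.behaviour_models:
        total = sum(m.probability for m in script.behaviour_models)
        if abs(total - 1.0) > PROB_SUM_TOL:
            findings.append(f"behaviour-model probabilities sum to {total:g}, not 1")
    else:
        findings.append("script defines no behaviour models")

    for i, model in enumerate(script.behaviour_models):
        for el in model.elements:
            names = [n for n, _ in el.items] if isinstance(el, SequenceSpec) else [el.activity_name]
            for name in names:
                if name not in script.activities:
                    findings.append(
                        f"behaviour model {i}: unknown activity {name!r}"
                    )

    for name in script.positive_noise:
        if name not in known_sensors:
            findings.append(
                f"noise sensor {name!r} not present in the context knowledge"
            )

    return findings
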