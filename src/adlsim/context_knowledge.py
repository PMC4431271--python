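"""Context knowledge: the simulated environment and its missing-noise models.

The context knowledge file is JSON with three top-level keys:

``objects``
    ``[{"name", "location", "attached_sensor"}, ...]`` — the objects of the
    environment, where they are and which sensor monitors each one;
``sensors``
    ``[{"name", "type"}, ...]`` — every sensor and its technology type
    (contact, tilt, pressure, sound, ...);
``error_models``
    ``{type: p, ...}`` — per sensor type, the probability ``p ∈ [0, 1]``
    that a real interaction produces *no* activation (missing noise).

Missing noise is a property of the sensor technology and monitoring
infrastructure, which is why it lives here rather than in the per-user ADL
script.  The complement of a reported user-object interaction recognition
accuracy (UoIR) calibrates ``p``: a contact-sensor deployment that captured
611 of 624 interactions (97.92%) justifies ``p = 1 - 611/624 ≈ 0.0208``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "ContextError",
    "SensorSpec",
    "ObjectSpec",
    "ContextKnowledge",
    "parse_context",
    "serialize_context",
    "missing_prob_for",
    "estimate_missing_prob",
]


class ContextError(ValueError):
    """Malformed or incoherent context knowledge document."""


@dataclass(frozen=True)
class SensorSpec:
    name: str
    sensor_type: str


@dataclass(frozen=True)
class ObjectSpec:
    name: str
    location: str
    attached_sensor: str


@dataclass
class ContextKnowledge:
    objects: list[ObjectSpec]
    sensors: list[SensorSpec]
    missing_noise: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sensors]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ContextError(f"duplicate sensor names: {dup}")
        for t, p in self.missing_noise.items():
            if not isinstance(p, (int, float)) or not 0.0 <= p <= 1.0:
                raise ContextError(f"missing probability {p!r} for type {t!r} outside [0, 1]")
        for s in self.sensors:
            if s.sensor_type not in self.missing_noise:
                raise ContextError(
                    f"sensor {s.name!r} has type {s.sensor_type!r} with no error model"
                )
        sensor_names = set(names)
        for obj in self.objects:
            if obj.attached_sensor not in sensor_names:
                raise ContextError(
                    f"object {obj.name!r} references unknown sensor {obj.attached_sensor!r}"
                )

    def sensor_names(self) -> set[str]:
        return {s.name for s in self.sensors}


def _require(mapping: dict, key: str, doc: str) -> object:
    if key not in mapping:
        raise ContextError(f"{doc} is missing required key {key!r}")
    return mapping[key]


def parse_context(json_text: str) -> ContextKnowledge:
    """Parse and validate a context-knowledge JSON document."""
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ContextError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ContextError("top level must be a JSON object")

    raw_objects = _require(doc, "objects", "context document")
    raw_sensors = _require(doc, "sensors", "context document")
    raw_errors = _require(doc, "error_models", "context document")
    if not isinstance(raw_objects, list) or not isinstance(raw_sensors, list):
        raise ContextError("'objects' and 'sensors' must be arrays")
    if not isinstance(raw_errors, dict):
        raise ContextError("'error_models' must be an object mapping type -> probability")

    sensors = [
        SensorSpec(
            name=str(_require(s, "name", "sensor entry")),
            sensor_type=str(_require(s, "type", "sensor entry")),
        )
        for s in raw_sensors
    ]
    objects = [
        ObjectSpec(
            name=str(_require(o, "name", "object entry")),
            location=str(_require(o, "location", "object entry")),
            attached_sensor=str(_require(o, "attached_sensor", "object entry")),
        )
        for o in raw_objects
    ]
    missing = {str(k): float(v) for k, v in raw_errors.items()}
    return ContextKnowledge(objects=objects, sensors=sensors, missing_noise=missing)


def serialize_context(ctx: ContextKnowledge) -> str:
    """Inverse of :func:`parse_context` (parse ∘ serialize is the identity)."""
    doc = {
        "objects": [
            {"name": o.name, "location": o.location, "attached_sensor": o.attached_sensor}
            for o in ctx.objects
        ],
        "sensors": [{"name": s.name, "type": s.sensor_type} for s in ctx.sensors],
        "error_models": dict(ctx.missing_noise),
    }
    return json.dumps(doc, indent=2) + "\n"


def missing_prob_for(ctx: ContextKnowledge, sensor_name: str) -> float:
    """Miss probability of a sensor, looked up through its type."""
    for s in ctx.sensors:
        if s.name == sensor_name:
            return ctx.missing_noise[s.sensor_type]
    raise KeyError(f"unknown sensor {sensor_name!r}")


def estimate_missing_prob(captured: int, total: int) -> float:
    """Calibrate a missing-noise probability from interaction counts.

    ``captured / total`` is the user-object interaction recognition
    accuracy (UoIR); the miss probability is its complement ``1 - UoIR``.
    """
    if total <= 0:
        raise ValueError("total interactions must be positive")
    if not 0 <= captured <= total:
        raise ValueError("captured must satisfy 0 <= captured <= total")
    return 1.0 - captured / total
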