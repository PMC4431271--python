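"""Self-contained example script/context bundles.

The bundles make the whole pipeline exercisable without any external data.
The ``paper-like`` profile mimics a single resident whose mornings start
with breakfast between 8 and 10 a.m., followed roughly a quarter of an
hour later by a shower, and whose dinner falls between 6:40 and 8:30 p.m.,
observed through eight binary object sensors (pan/plate/cup cupboards,
fridge, microwave, hall toilet door, freezer, grocery cupboard) over five
days.  Exact pattern probabilities and lapses are the fixture's own
choices, documented inline in the script text.
"""

from __future__ import annotations

from dataclasses import dataclass

from .adl_script import parse_adl_script, validate_script
from .context_knowledge import parse_context

__all__ = ["FixtureBundle", "make_fixture", "PROFILES"]


@dataclass(frozen=True)
class FixtureBundle:
    """A coherent ADL-script / context-knowledge pair, as source text."""

    adl_script: str
    context_json: str
    description: str


_MINIMAL_SCRIPT = """\
# Smallest coherent world: one activity, one sensor, one kind of day.
DAYS
1

ACTIVITIES
SwitchLamp 1
1.0 lampSens@0

BEHAVIOURS
Prob 1.0
S 09:00 - 10:00 SwitchLamp@0

NOISE
"""

_MINIMAL_CONTEXT = """\
{
  "objects": [
    {"name": "lamp", "location": "lounge", "attached_sensor": "lampSens"}
  ],
  "sensors": [
    {"name": "lampSens", "type": "contact"}
  ],
  "error_models": {"contact": 0.0}
}
"""

# Breakfast 8-10 a.m., shower ~15 min after breakfast ends, dinner
# 6:40-8:30 p.m.; lapses within activities span a few minutes so that an
# activity stays well inside a five-minute histogram bin or its neighbours.
_PAPER_LIKE_SCRIPT = """\
# One resident, five days, three daily activities seen through eight
# binary object sensors.  Pattern probabilities and lapses are this
# fixture's own choices; slots follow the typical day described above.
DAYS
5

ACTIVITIES
PrepareBreakfast 2
0.6 cupCupboardSens@0 fridgeSens@30 plateCupboardSens@45 microwaveSens@60
0.4 cupCupboardSens@0 groceryCupboardSens@40 fridgeSens@35 plateCupboardSens@50
TakeShower 1
1.0 hallToiletDoorSens@0 hallToiletDoorSens@600
PrepareDinner 2
0.5 panCupboardSens@0 fridgeSens@40 freezerSens@60 microwaveSens@180 plateCupboardSens@120
0.5 panCupboardSens@0 groceryCupboardSens@30 fridgeSens@45 microwaveSens@150 plateCupboardSens@90

BEHAVIOURS
Prob 1.0
S 08:00 - 10:00 PrepareBreakfast@0 TakeShower@900
S 18:40 - 20:30 PrepareDinner@0

NOISE
fridgeSens 0.02
hallToiletDoorSens 0.01
"""

_PAPER_LIKE_CONTEXT = """\
{
  "objects": [
    {"name": "panCupboard", "location": "kitchen", "attached_sensor": "panCupboardSens"},
    {"name": "plateCupboard", "location": "kitchen", "attached_sensor": "plateCupboardSens"},
    {"name": "cupCupboard", "location": "kitchen", "attached_sensor": "cupCupboardSens"},
    {"name": "fridge", "location": "kitchen", "attached_sensor": "fridgeSens"},
    {"name": "microwave", "location": "kitchen", "attached_sensor": "microwaveSens"},
    {"name": "hallToiletDoor", "location": "hall", "attached_sensor": "hallToiletDoorSens"},
    {"name": "freezer", "location": "kitchen", "attached_sensor": "freezerSens"},
    {"name": "groceryCupboard", "location": "kitchen", "attached_sensor": "groceryCupboardSens"}
  ],
  "sensors": [
    {"name": "panCupboardSens", "type": "contact"},
    {"name": "plateCupboardSens", "type": "contact"},
    {"name": "cupCupboardSens", "type": "contact"},
    {"name": "fridgeSens", "type": "contact"},
    {"name": "microwaveSens", "type": "tilt"},
    {"name": "hallToiletDoorSens", "type": "contact"},
    {"name": "freezerSens", "type": "contact"},
    {"name": "groceryCupboardSens", "type": "contact"}
  ],
  "error_models": {"contact": 0.0208, "tilt": 0.0556}
}
"""

PROFILES = {
    "minimal": FixtureBundle(
        _MINIMAL_SCRIPT,
        _MINIMAL_CONTEXT,
        "one activity, one sensor, one day; no noise of either kind",
    ),
    "paper-like": FixtureBundle(
        _PAPER_LIKE_SCRIPT,
        _PAPER_LIKE_CONTEXT,
        "three daily activities, eight sensors, five days, calibrated missing noise",
    ),
}


def make_fixture(profile: str = "paper-like") -> FixtureBundle:
    """Return a bundled script/context pair; guaranteed to validate cleanly."""
    try:
        bundle = PROFILES[profile]
    except KeyError:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    script = parse_adl_script(bundle.adl_script)
    ctx = parse_context(bundle.context_json)
    findings = validate_script(script, ctx)
    assert not findings, f"bundled fixture {profile!r} is incoherent: {findings}"
    return bundle
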