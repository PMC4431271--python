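"""The simulation loop: from an ADL script to a labelled sensor-event dataset.

Each simulated day proceeds in a fixed order so that one seeded random
stream reproduces the dataset byte for byte:

1. **Positive noise** — for every sensor with a per-hour activation
   probability above zero, each of the 24 hours gets an independent
   Bernoulli draw; an activation lands uniformly inside its hour and is
   labelled ``None``.
2. **Behaviour model** — one day model is drawn according to the models'
   occurrence probabilities.
3. **Elements in list order** — each sequence draws a uniform start inside
   its time slot for its first activity; later activities start a sampled
   lapse after the previous activity's end.  Alterations first draw their
   Bernoulli and, when selected, run as one-activity sequences.  Within an
   activity one sensor-activation pattern is drawn and its steps are laid
   out with sampled lapses.
4. **Missing noise** — once the day's schedule is fixed, every activity
   event is independently dropped with its sensor's miss probability.
   Dropping never reschedules the surviving events, so the time structure
   of the day is independent of sensor reliability.

Time lapses are drawn from a Gaussian whose mean is the scripted lapse and
whose standard deviation defaults to 25% of the mean; negative draws are
resampled (up to ``max_resample`` times, then clamped to zero) so sensor
order within an activity is never inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np

from .adl_script import (
    ADLScript,
    ActivityDefinition,
    AlterationSpec,
    BehaviourModel,
    SequenceSpec,
    validate_script,
)
from .context_knowledge import ContextKnowledge, missing_prob_for

__all__ = [
    "SimulationConfig",
    "SensorEvent",
    "ActivityInstance",
    "LabelledDataset",
    "run_simulation",
    "generate_positive_noise_day",
    "select_behaviour_model",
    "select_pattern",
    "sample_time_lapse",
    "execute_sequence",
    "execute_alteration",
    "apply_missing_noise",
]

#: marker values carried by events (start+end for single-event instances)
MARKER_NONE = ""
MARKER_START = "start"
MARKER_END = "end"
MARKER_BOTH = "start+end"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulation loop.

    ``start_date`` defaults to a fixed date rather than "today" so that a
    fixed seed reproduces the dataset exactly; pass ``date.today()`` to
    mimic launching the original tool.
    """

    seed: int = 0
    sd_fraction: float = 0.25
    start_date: date = date(2015, 1, 1)
    max_resample: int = 100

    def __post_init__(self) -> None:
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")
        if self.max_resample < 0:
            raise ValueError("max_resample must be >= 0")


@dataclass
class SensorEvent:
    """One timestamped sensor activation.

    ``label`` is the activity name, or ``None`` for noise events (written
    as the literal string ``None`` in CSV).  ``marker`` flags activity
    boundaries.  ``instance_index`` links an event to its activity
    instance; it is bookkeeping, excluded from equality and not persisted.
    """

    timestamp: datetime
    sensor_name: str
    label: str | None
    marker: str = MARKER_NONE
    instance_index: int | None = field(default=None, compare=False, repr=False)

    @property
    def is_noise(self) -> bool:
        return self.label is None


@dataclass
class ActivityInstance:
    """One execution of an activity; boundary times come from the pre-drop
    schedule, so they are unaffected by missing noise."""

    activity_name: str
    start_time: datetime
    end_time: datetime
    chosen_pattern_index: int

    def __post_init__(self) -> None:
        if self.start_time > self.end_time:
            raise ValueError("instance start must not exceed its end")


@dataclass
class LabelledDataset:
    """Time-ordered labelled events plus the activity instances behind them."""

    events: list[SensorEvent]
    instances: list[ActivityInstance]
    span: tuple[date, date]

    def sensors(self) -> list[str]:
        return sorted({e.sensor_name for e in self.events})


# ---------------------------------------------------------------------------
# primitive draws
# ---------------------------------------------------------------------------


def sample_time_lapse(mean_s: float, cfg: SimulationConfig, rng: np.random.Generator) -> float:
    """Gaussian lapse with σ = ``sd_fraction``·mean, never negative.

    A zero mean gives σ = 0, hence exactly 0.  Negative draws are
    resampled up to ``cfg.max_resample`` times and finally clamped to 0.
    """
    if mean_s < 0:
        raise ValueError("mean lapse must be >= 0")
    if mean_s == 0:
        return 0.0
    sd = cfg.sd_fraction * mean_s
    for _ in range(cfg.max_resample + 1):
        draw = rng.normal(mean_s, sd)
        if draw >= 0:
            return float(draw)
    return 0.0


def _categorical(probs: list[float], rng: np.random.Generator) -> int:
    # probabilities are pre-validated to sum to 1 (±1e-6); the final index
    # absorbs any residual so the draw is always well defined
    r = rng.random()
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if r < acc:
            return i
    return len(probs) - 1


def select_behaviour_model(
    models: list[BehaviourModel], rng: np.random.Generator
) -> BehaviourModel:
    """Draw one day model according to the models' occurrence probabilities."""
    if not models:
        raise ValueError("no behaviour models to select from")
    return models[_categorical([m.probability for m in models], rng)]


def select_pattern(activity: ActivityDefinition, rng: np.random.Generator):
    """Draw one sensor-activation pattern of ``activity``; returns
    ``(index, pattern)``."""
    idx = _categorical([p.probability for p in activity.patterns], rng)
    return idx, activity.patterns[idx]


# ---------------------------------------------------------------------------
# noise generation
# ---------------------------------------------------------------------------


def generate_positive_noise_day(
    day: date, noise: dict[str, float], rng: np.random.Generator
) -> list[SensorEvent]:
    """Spurious activations for one day: per sensor, per hour, at most one
    event, placed uniformly inside the hour and labelled ``None``.

    Sensors are visited in specification order and hours 0..23 within each
    sensor, which pins down the random-stream consumption order.
    """
    midnight = datetime.combine(day, datetime.min.time())
    events: list[SensorEvent] = []
    for sensor, p in noise.items():
        if p <= 0:
            continue
        for hour in range(24):
            if rng.random() < p:
                offset = int(rng.uniform(0.0, 3600.0))  # whole seconds in [0, 3599]
                ts = midnight + timedelta(seconds=hour * 3600 + offset)
                events.append(SensorEvent(ts, sensor, label=None))
    return events


def apply_missing_noise(
    events: list[SensorEvent], ctx: ContextKnowledge, rng: np.random.Generator
) -> list[SensorEvent]:
    """Drop each activity event with its sensor's miss probability.

    Noise events are spurious activations and are never subject to missing
    noise.  Surviving events keep their timestamps.
    """
    kept: list[SensorEvent] = []
    for ev in events:
        if ev.is_noise:
            kept.append(ev)
            continue
        if rng.random() >= missing_prob_for(ctx, ev.sensor_name):
            kept.append(ev)
    return kept


# ---------------------------------------------------------------------------
# schedule execution
# ---------------------------------------------------------------------------


def _execute_activity(
    name: str,
    start_s: float,
    midnight: datetime,
    script: ADLScript,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    instance_index: int,
) -> tuple[list[SensorEvent], ActivityInstance, float]:
    """Lay out one activity instance starting at ``start_s`` seconds after
    midnight; returns (events, instance, end_s of the pre-drop schedule)."""
    activity = script.activities[name]
    pat_idx, pattern = select_pattern(activity, rng)
    t = start_s
    events: list[SensorEvent] = []
    for i, step in enumerate(pattern.steps):
        if i > 0:
            t += sample_time_lapse(step.lapse_s, cfg, rng)
        ts = midnight + timedelta(seconds=round(t))
        events.append(
            SensorEvent(ts, step.sensor_name, label=name, instance_index=instance_index)
        )
    instance = ActivityInstance(
        activity_name=name,
        start_time=events[0].timestamp,
        end_time=events[-1].timestamp,
        chosen_pattern_index=pat_idx,
    )
    return events, instance, t


def execute_sequence(
    seq: SequenceSpec,
    script: ADLScript,
    ctx: ContextKnowledge,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    day: date = date(2015, 1, 1),
    _instance_offset: int = 0,
) -> tuple[list[SensorEvent], list[ActivityInstance]]:
    """Execute one sequence for ``day``.

    The first activity starts uniformly inside the time slot; each later
    activity starts a Gaussian-sampled lapse after the previous activity's
    end.  Events are returned *before* missing noise; the caller applies
    :func:`apply_missing_noise` over the whole day so that dropped events
    do not shift the schedule.  Later activities may overrun the slot.
    """
    midnight = datetime.combine(day, datetime.min.time())
    events: list[SensorEvent] = []
    instances: list[ActivityInstance] = []
    if not seq.items:
        return events, instances
    t = rng.uniform(seq.slot.start_s, seq.slot.end_s)
    for name, lapse in seq.items:
        if name not in script.activities:
            raise KeyError(f"sequence references unknown activity {name!r}")
        if instances:  # later activities: lapse from the previous end
            t = prev_end + sample_time_lapse(lapse, cfg, rng)
        ev, inst, prev_end = _execute_activity(
            name, t, midnight, script, cfg, rng, _instance_offset + len(instances)
        )
        events.extend(ev)
        instances.append(inst)
    return events, instances


def execute_alteration(
    alt: AlterationSpec,
    script: ADLScript,
    ctx: ContextKnowledge,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    day: date = date(2015, 1, 1),
    _instance_offset: int = 0,
) -> tuple[list[SensorEvent], list[ActivityInstance]]:
    """With probability ``alt.probability``, run the activity as a
    one-item sequence inside the alteration's slot; otherwise nothing."""
    if alt.activity_name not in script.activities:
        raise KeyError(f"alteration references unknown activity {alt.activity_name!r}")
    if rng.random() >= alt.probability:
        return [], []
    seq = SequenceSpec(alt.slot, ((alt.activity_name, 0),))
    return execute_sequence(seq, script, ctx, cfg, rng, day, _instance_offset)


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------


def _assign_markers(day_events: list[SensorEvent]) -> None:
    """Mark the first/last surviving event of every instance (in place).

    A single surviving event carries the combined ``start+end`` marker.
    Instances whose events were all dropped simply get no markers.
    """
    by_instance: dict[int, list[SensorEvent]] = {}
    for ev in day_events:
        if ev.instance_index is not None:
            by_instance.setdefault(ev.instance_index, []).append(ev)
    for evs in by_instance.values():
        if len(evs) == 1:
            evs[0].marker = MARKER_BOTH
        else:
            evs[0].marker = MARKER_START
            evs[-1].marker = MARKER_END


def run_simulation(
    script: ADLScript, ctx: ContextKnowledge, cfg: SimulationConfig
) -> LabelledDataset:
    """Simulate ``script.days`` days and return the labelled dataset.

    The script is re-validated against the context; any finding is fatal.
    Events are globally sorted by timestamp with activity events before
    noise events at equal seconds, and emission order as the final tie-break
    (which preserves pattern order within every instance).
    """
    findings = validate_script(script, ctx)
    if findings:
        raise ValueError("invalid script/context: " + "; ".join(findings))

    rng = np.random.default_rng(cfg.seed)
    all_events: list[SensorEvent] = []
    all_instances: list[ActivityInstance] = []

    for day_idx in range(script.days):
        day = cfg.start_date + timedelta(days=day_idx)
        noise_events = generate_positive_noise_day(day, script.positive_noise, rng)
        model = select_behaviour_model(script.behaviour_models, rng)

        day_events: list[SensorEvent] = []
        day_instances: list[ActivityInstance] = []
        for element in model.elements:
            offset = len(all_instances) + len(day_instances)
            if isinstance(element, SequenceSpec):
                ev, inst = execute_sequence(element, script, ctx, cfg, rng, day, offset)
            else:
                ev, inst = execute_alteration(element, script, ctx, cfg, rng, day, offset)
            day_events.extend(ev)
            day_instances.extend(inst)

        day_events = apply_missing_noise(day_events, ctx, rng)
        _assign_markers(day_events)
        all_events.extend(day_events)
        all_events.extend(noise_events)
        all_instances.extend(day_instances)

    order = {id(ev): i for i, ev in enumerate(all_events)}
    all_events.sort(key=lambda ev: (ev.timestamp, ev.is_noise, order[id(ev)]))
    span = (cfg.start_date, cfg.start_date + timedelta(days=script.days - 1))
    return LabelledDataset(events=all_events, instances=all_instances, span=span)
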