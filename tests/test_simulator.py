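"""Simulation loop: forced counts, draw frequencies, lapse distribution,
noise models, determinism, ordering and marker bookkeeping."""

from datetime import date, timedelta

import numpy as np
import pytest
from scipy import stats

import adlsim
from adlsim.simulator import MARKER_BOTH, MARKER_END, MARKER_START, SimulationConfig

SCRIPT_TMPL = """\
DAYS
{days}
ACTIVITIES
Task 1
1.0 aSens@0 bSens@60 cSens@60
BEHAVIOURS
Prob 1.0
S 09:00 - 10:00 Task@0
NOISE
{noise}
"""

CTX_TEXT = """
{"objects": [], "sensors": [
    {"name": "aSens", "type": "contact"},
    {"name": "bSens", "type": "contact"},
    {"name": "cSens", "type": "contact"},
    {"name": "noiseSens", "type": "contact"}],
 "error_models": {"contact": 0.0}}
"""


def make_world(days=1, noise=""):
    script = adlsim.parse_adl_script(SCRIPT_TMPL.format(days=days, noise=noise))
    ctx = adlsim.parse_context(CTX_TEXT)
    return script, ctx


# ---------------------------------------------------------------------------
# forced event counts
# ---------------------------------------------------------------------------


def test_single_day_forced_counts():
    script, ctx = make_world(days=1)
    ds = adlsim.run_simulation(script, ctx, SimulationConfig(seed=7))
    assert len(ds.events) == 3
    assert len(ds.instances) == 1
    assert [e.marker for e in ds.events] == [MARKER_START, "", MARKER_END]
    assert all(e.label == "Task" for e in ds.events)
    assert ds.span == (date(2015, 1, 1), date(2015, 1, 1))


def test_five_days_forced_counts():
    script, ctx = make_world(days=5)
    ds = adlsim.run_simulation(script, ctx, SimulationConfig(seed=7))
    assert len(ds.events) == 15
    assert len(ds.instances) == 5
    assert ds.span == (date(2015, 1, 1), date(2015, 1, 5))


def test_certain_noise_adds_24_none_events_per_day():
    script, ctx = make_world(days=1, noise="noiseSens 1.0")
    ds = adlsim.run_simulation(script, ctx, SimulationConfig(seed=7))
    noise = [e for e in ds.events if e.label is None]
    labelled = [e for e in ds.events if e.label is not None]
    assert len(noise) == 24 and len(labelled) == 3
    assert all(e.marker == "" for e in noise)


# ---------------------------------------------------------------------------
# positive noise generation
# ---------------------------------------------------------------------------


def test_noise_zero_probability_empty():
    rng = np.random.default_rng(0)
    assert adlsim.generate_positive_noise_day(date(2015, 1, 1), {"s": 0.0}, rng) == []


def test_noise_certain_one_event_inside_each_hour():
    rng = np.random.default_rng(0)
    events = adlsim.generate_positive_noise_day(date(2015, 1, 1), {"s": 1.0}, rng)
    assert len(events) == 24
    for k, ev in enumerate(events):
        assert ev.label is None
        secs = ev.timestamp.hour * 3600 + ev.timestamp.minute * 60 + ev.timestamp.second
        assert k * 3600 <= secs < (k + 1) * 3600


def test_noise_rate_recovered():
    """p = 0.1 per hour -> 2.4 events/day expected; empirical mean in [2.2, 2.6]."""
    rng = np.random.default_rng(42)
    counts = [
        len(adlsim.generate_positive_noise_day(date(2015, 1, 1), {"s": 0.1}, rng))
        for _ in range(1000)
    ]
    assert 2.2 <= np.mean(counts) <= 2.6


# ---------------------------------------------------------------------------
# categorical draws
# ---------------------------------------------------------------------------


def test_single_model_always_selected():
    model = adlsim.BehaviourModel(1.0, ())
    rng = np.random.default_rng(0)
    assert all(adlsim.select_behaviour_model([model], rng) is model for _ in range(50))


def test_empty_model_list_rejected():
    with pytest.raises(ValueError):
        adlsim.select_behaviour_model([], np.random.default_rng(0))


@pytest.mark.parametrize("probs", [(2 / 7, 5 / 7), (0.6, 0.4)])
def test_behaviour_selection_frequencies(probs):
    """Empirical selection frequency matches the stated probability ±0.02
    over 10^4 draws (binomial SE ≈ 0.005)."""
    models = [adlsim.BehaviourModel(p, ()) for p in probs]
    rng = np.random.default_rng(3)
    hits = sum(adlsim.select_behaviour_model(models, rng) is models[0] for _ in range(10**4))
    assert abs(hits / 10**4 - probs[0]) < 0.02


def test_pattern_selection_frequencies():
    step = (adlsim.SensorActivationStep("s", 0),)
    act = adlsim.ActivityDefinition(
        "A",
        (
            adlsim.SensorActivationPattern(0.5, step),
            adlsim.SensorActivationPattern(0.5, step),
        ),
    )
    rng = np.random.default_rng(4)
    hits = sum(adlsim.select_pattern(act, rng)[0] == 0 for _ in range(10**4))
    assert abs(hits / 10**4 - 0.5) < 0.02
    single = adlsim.ActivityDefinition("B", (adlsim.SensorActivationPattern(1.0, step),))
    assert all(adlsim.select_pattern(single, rng)[0] == 0 for _ in range(100))


# ---------------------------------------------------------------------------
# Gaussian time lapses
# ---------------------------------------------------------------------------


def test_zero_mean_lapse_is_exactly_zero():
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(0)
    assert all(adlsim.sample_time_lapse(0, cfg, rng) == 0.0 for _ in range(100))


def test_lapse_moments_sigma_quarter_of_mean():
    """mean 20 -> N(20, 5): sample mean in [19.9, 20.1], SD in [4.9, 5.1]
    over 10^5 draws."""
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(12345)
    draws = np.array([adlsim.sample_time_lapse(20, cfg, rng) for _ in range(10**5)])
    assert 19.9 <= draws.mean() <= 20.1
    assert 4.9 <= draws.std(ddof=1) <= 5.1


def test_lapse_never_negative():
    """Negative draws are resampled/clamped: none survive, even at mean 1
    where the raw Gaussian goes negative with probability ~3e-5."""
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(99)
    assert all(adlsim.sample_time_lapse(1, cfg, rng) >= 0 for _ in range(10**6))


def test_negative_mean_rejected():
    with pytest.raises(ValueError):
        adlsim.sample_time_lapse(-1, SimulationConfig(), np.random.default_rng(0))


# ---------------------------------------------------------------------------
# sequences and alterations
# ---------------------------------------------------------------------------

SEQ_SCRIPT = """\
DAYS
1
ACTIVITIES
MakeCoffe 1
1.0 coffeeSens@0 cookerSens@20
WatchTelevision 1
1.0 tvSens@0 tvSens@120
BrushTeeth 1
1.0 toothSens@0 tapSens@30
BEHAVIOURS
Prob 1.0
S 9:00 - 10:00 MakeCoffe@0 WatchTelevision@30 BrushTeeth@1800
NOISE
"""

SEQ_CTX = """
{"objects": [], "sensors": [
    {"name": "coffeeSens", "type": "contact"}, {"name": "cookerSens", "type": "contact"},
    {"name": "tvSens", "type": "contact"}, {"name": "toothSens", "type": "contact"},
    {"name": "tapSens", "type": "contact"}],
 "error_models": {"contact": 0.0}}
"""


def seq_world():
    return adlsim.parse_adl_script(SEQ_SCRIPT), adlsim.parse_context(SEQ_CTX)


def test_sequence_order_slot_and_lapse_distribution():
    script, ctx = seq_world()
    seq = script.behaviour_models[0].elements[0]
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(2024)
    gaps = []
    for _ in range(1000):
        events, instances = adlsim.execute_sequence(seq, script, ctx, cfg, rng)
        assert [i.activity_name for i in instances] == [
            "MakeCoffe",
            "WatchTelevision",
            "BrushTeeth",
        ]
        start = instances[0].start_time
        secs = start.hour * 3600 + start.minute * 60 + start.second
        assert 9 * 3600 <= secs < 10 * 3600
        gaps.append((instances[2].start_time - instances[1].end_time).total_seconds())
    # BrushTeeth starts N(1800, 450) after WatchTelevision ends
    gaps = np.asarray(gaps)
    assert abs(gaps.mean() - 1800) < 3 * 450 / np.sqrt(len(gaps))
    assert 0.9 * 450 < gaps.std(ddof=1) < 1.1 * 450


def test_empty_sequence_produces_nothing():
    script, ctx = seq_world()
    seq = adlsim.SequenceSpec(adlsim.TimeSlot(0, 3600), ())
    events, instances = adlsim.execute_sequence(
        seq, script, ctx, SimulationConfig(), np.random.default_rng(0)
    )
    assert events == [] and instances == []


def test_sequence_start_uniform_over_slot():
    """First-activity starts over 10^4 runs pass a KS uniformity check (α=0.01)."""
    script, ctx = seq_world()
    seq = adlsim.SequenceSpec(adlsim.TimeSlot(9 * 3600, 10 * 3600), (("MakeCoffe", 0),))
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(7)
    starts = []
    for _ in range(10**4):
        _, instances = adlsim.execute_sequence(seq, script, ctx, cfg, rng)
        s = instances[0].start_time
        starts.append(s.hour * 3600 + s.minute * 60 + s.second)
    # rounding to whole seconds is negligible over a 3600 s slot
    u = (np.asarray(starts) - 9 * 3600) / 3600
    assert stats.kstest(u, "uniform").pvalue > 0.01


@pytest.mark.parametrize("prob, lo, hi", [(0.0, 0, 0), (1.0, 10**4, 10**4)])
def test_alteration_degenerate_probabilities(prob, lo, hi):
    script, ctx = seq_world()
    alt = adlsim.AlterationSpec(prob, adlsim.TimeSlot(8 * 3600, 9 * 3600), "MakeCoffe")
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(11)
    executed = sum(
        bool(adlsim.execute_alteration(alt, script, ctx, cfg, rng)[1]) for _ in range(10**4)
    )
    assert lo <= executed <= hi


def test_alteration_half_probability():
    script, ctx = seq_world()
    alt = adlsim.AlterationSpec(0.5, adlsim.TimeSlot(8 * 3600, 9 * 3600), "MakeCoffe")
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(13)
    executed = sum(
        bool(adlsim.execute_alteration(alt, script, ctx, cfg, rng)[1]) for _ in range(10**4)
    )
    assert abs(executed / 10**4 - 0.5) < 0.02


# ---------------------------------------------------------------------------
# missing noise
# ---------------------------------------------------------------------------


def _flat_events(n, sensor="aSens"):
    from datetime import datetime

    base = datetime(2015, 1, 1)
    return [
        adlsim.SensorEvent(base + timedelta(seconds=i), sensor, "Task") for i in range(n)
    ]


def test_missing_noise_zero_is_identity():
    ctx = adlsim.parse_context(CTX_TEXT)
    events = _flat_events(200)
    out = adlsim.apply_missing_noise(events, ctx, np.random.default_rng(0))
    assert out == events


def test_missing_noise_one_drops_everything():
    ctx = adlsim.parse_context(CTX_TEXT.replace('"contact": 0.0', '"contact": 1.0'))
    assert adlsim.apply_missing_noise(_flat_events(200), ctx, np.random.default_rng(0)) == []


def test_missing_noise_retention_rate():
    """miss 0.0311 (overall UoIR complement): retention over 10^5 events
    lands in [96.7%, 97.1%]."""
    ctx = adlsim.parse_context(CTX_TEXT.replace('"contact": 0.0', '"contact": 0.0311'))
    out = adlsim.apply_missing_noise(_flat_events(10**5), ctx, np.random.default_rng(5))
    assert 0.967 <= len(out) / 10**5 <= 0.971


def test_missing_noise_never_drops_noise_events():
    ctx = adlsim.parse_context(CTX_TEXT.replace('"contact": 0.0', '"contact": 1.0'))
    from datetime import datetime

    noise = [adlsim.SensorEvent(datetime(2015, 1, 1), "aSens", None)]
    assert adlsim.apply_missing_noise(noise, ctx, np.random.default_rng(0)) == noise


# ---------------------------------------------------------------------------
# whole-dataset invariants
# ---------------------------------------------------------------------------


def test_determinism_same_seed_same_dataset(paper_pair):
    script, ctx = paper_pair
    a = adlsim.run_simulation(script, ctx, SimulationConfig(seed=33))
    b = adlsim.run_simulation(script, ctx, SimulationConfig(seed=33))
    assert a.events == b.events
    assert a.instances == b.instances


def test_label_conservation(paper_pair):
    """Every None-labelled event is a positive-noise event and vice versa;
    with all noise probabilities zero, no None labels appear."""
    script, ctx = paper_pair
    ds = adlsim.run_simulation(script, ctx, SimulationConfig(seed=9))
    n_none = sum(e.label is None for e in ds.events)
    assert all((e.instance_index is None) == (e.label is None) for e in ds.events)
    quiet = adlsim.ADLScript(
        script.days, script.activities, script.behaviour_models, {}
    )
    ds_quiet = adlsim.run_simulation(quiet, ctx, SimulationConfig(seed=9))
    assert sum(e.label is None for e in ds_quiet.events) == 0
    assert n_none >= 0


def test_events_sorted_and_pattern_order_preserved(paper_pair):
    script, ctx = paper_pair
    for seed in range(5):
        ds = adlsim.run_simulation(script, ctx, SimulationConfig(seed=seed))
        stamps = [e.timestamp for e in ds.events]
        assert stamps == sorted(stamps)
        # within an instance, sensor order must match the chosen pattern
        by_inst = {}
        for ev in ds.events:
            if ev.instance_index is not None:
                by_inst.setdefault(ev.instance_index, []).append(ev.sensor_name)
        for idx, sensors in by_inst.items():
            inst = ds.instances[idx]
            pattern = script.activities[inst.activity_name].patterns[
                inst.chosen_pattern_index
            ]
            expected = [s.sensor_name for s in pattern.steps]
            # missing noise only deletes; order is a subsequence of the pattern
            it = iter(expected)
            assert all(s in it for s in sensors)


def test_marker_consistency(paper_pair):
    script, ctx = paper_pair
    ds = adlsim.run_simulation(script, ctx, SimulationConfig(seed=17))
    by_inst = {}
    for ev in ds.events:
        if ev.instance_index is not None:
            by_inst.setdefault(ev.instance_index, []).append(ev)
    for events in by_inst.values():
        if len(events) == 1:
            assert events[0].marker == MARKER_BOTH
        else:
            assert events[0].marker == MARKER_START
            assert events[-1].marker == MARKER_END
            assert all(e.marker == "" for e in events[1:-1])
        assert events[0].timestamp <= events[-1].timestamp
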