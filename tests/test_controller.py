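"""pH-stat decision logic: dosing rule, adaptation, manual mode, PID, loop."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phstat.controller import (Action, ControlConfig, ControlState, LogRecord,
                               adapt, decide, manual_mode, pid_step, run_loop,
                               summarize)
from phstat.ocr import Reading
from phstat.plant import (PERISTALTIC_NOISE, PlantFrameSource,
                          VirtualPeristalticPump, inert_plant,
                          reference_calibration, reference_geometry,
                          reference_style, tempo_reference_plant)
from phstat.pumps import PeristalticPumpSpec


def fresh(config=None):
    config = config or ControlConfig()
    return config, ControlState.initial(config)


# ------------------------------------------------------------------ decide

def test_dose_when_below_setpoint_and_interval_elapsed():
    config, state = fresh()
    state.last_dose_time = 0.0
    assert decide(Reading(10.50, True, 6.0), state, config, 6.0) is Action.DOSE
    assert state.unit_volume == 2.0


def test_no_dose_above_or_at_setpoint():
    config, state = fresh()
    assert decide(Reading(10.60, True, 1.0), state, config, 1.0) is Action.NONE
    assert decide(Reading(10.55, True, 2.0), state, config, 2.0) is Action.NONE


def test_no_dose_before_min_interval():
    config, state = fresh()
    state.last_dose_time = 0.0
    assert decide(Reading(10.40, True, 3.0), state, config, 3.0) is Action.NONE
    assert decide(Reading(10.40, True, 5.0), state, config, 5.0) is Action.DOSE


def test_invalid_reading_never_doses_and_eventually_alarms():
    config, state = fresh()
    state.last_valid_reading = Reading(10.40, True, 0.0)
    bad = Reading(float("nan"), False, 5.0)
    assert decide(bad, state, config, 5.0) is Action.NONE
    assert decide(Reading(float("nan"), False, 10.0),
                  state, config, 10.0) is Action.ALARM
    assert state.alarm


@given(st.lists(st.tuples(st.booleans(), st.floats(9.0, 12.0)), min_size=1,
                max_size=60))
def test_safety_no_dose_from_invalid_above_or_early(stream):
    """Fuzzed reading streams: every DOSE is justified by the three gates."""
    config, state = fresh()
    for k, (valid, value) in enumerate(stream):
        now = float(k)
        gap_ok = now - state.last_dose_time >= state.min_interval
        reading = Reading(value if valid else float("nan"), valid, now)
        action = decide(reading, state, config, now)
        if action is Action.DOSE:
            assert valid and value < config.setpoint and gap_ok
            state.last_dose_time = now


def test_liveness_doses_at_exact_interval_spacing():
    """pH pinned below setpoint: doses at exactly min_interval spacing."""
    config = ControlConfig(adapt_enabled=False)
    state = ControlState.initial(config)
    dose_times = []
    for k in range(40):
        now = float(k)
        if decide(Reading(10.40, True, now), state, config, now) is Action.DOSE:
            state.last_dose_time = now
            dose_times.append(now)
    gaps = [b - a for a, b in zip(dose_times, dose_times[1:])]
    assert gaps and all(g == config.min_interval for g in gaps)


# ------------------------------------------------------------------- adapt

def test_adaptation_halves_volume_after_quiet_spell():
    config, state = fresh()
    state.last_dose_time = 0.0
    adapt(state, config, now=20.0)          # 4 x 5 s quiet windows elapsed
    assert state.unit_volume == 1.0
    assert state.min_interval == 10.0


def test_adaptation_requires_full_quiet_spell():
    config, state = fresh()
    state.last_dose_time = 0.0
    adapt(state, config, now=19.0)
    assert state.unit_volume == 2.0


def test_adaptation_bottoms_out_at_floor():
    config, state = fresh()
    state.last_dose_time = 0.0
    t = 0.0
    for _ in range(10):
        t += 4 * state.min_interval
        adapt(state, config, now=t)
    assert state.unit_volume == config.unit_volume_floor == 0.5
    assert state.min_interval == config.interval_cap


def test_deep_excursion_reverses_one_adaptation_step():
    config, state = fresh()
    state.unit_volume, state.min_interval = 0.5, 20.0
    deep = Reading(10.45, True, 100.0)      # >0.05 below setpoint
    adapt(state, config, now=100.0, dosed=True, reading=deep)
    assert state.unit_volume == 1.0
    assert state.min_interval == 10.0


def test_shallow_dose_does_not_reverse():
    config, state = fresh()
    state.unit_volume, state.min_interval = 0.5, 20.0
    adapt(state, config, now=100.0, dosed=True,
          reading=Reading(10.53, True, 100.0))
    assert state.unit_volume == 0.5


def test_fresh_state_immediate_dose_no_adaptation():
    config, state = fresh()
    adapt(state, config, now=0.0, dosed=True,
          reading=Reading(10.54, True, 0.0))
    assert state.unit_volume == config.initial_unit_volume
    assert state.min_interval == config.min_interval


# ------------------------------------------------------------- manual mode

def test_manual_mode_volume_is_rate_times_elapsed():
    pump = VirtualPeristalticPump(PeristalticPumpSpec(coefficient=8.167e-4))
    doses = manual_mode([("start", 0.0), ("stop", 2.0)], pump)
    assert len(doses) == 1
    assert doses[0][1] == pytest.approx(8.167e-4 * 2000.0)


def test_manual_mode_zero_elapsed_and_additivity():
    pump = VirtualPeristalticPump(PeristalticPumpSpec(coefficient=8.167e-4))
    assert manual_mode([("start", 1.0), ("stop", 1.0)], pump)[0][1] == 0.0
    two_presses = manual_mode([("start", 0), ("stop", 1),
                               ("start", 5), ("stop", 6)], pump)
    one_press = manual_mode([("start", 0), ("stop", 2)], pump)
    assert sum(v for _, v in two_presses) == pytest.approx(one_press[0][1])


def test_manual_mode_stop_without_start_is_noop():
    pump = VirtualPeristalticPump(PeristalticPumpSpec(coefficient=8.167e-4))
    assert manual_mode([("stop", 1.0)], pump) == []


# --------------------------------------------------------------------- PID

def test_pid_trivial_outputs():
    assert pid_step(0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0) == (0.0, 0.0)
    rate, _ = pid_step(0.1, 0.0, 0.1, kp=1.0, ki=0.0, kd=0.0, dt=1.0)
    assert rate == pytest.approx(0.1)


def test_pid_clamps_and_freezes_integral():
    rate, integral = pid_step(-1.0, 0.0, 0.0, kp=1.0, ki=1.0, kd=0.0, dt=1.0)
    assert rate == 0.0 and integral == 0.0          # anti-windup: frozen
    rate, integral = pid_step(5.0, 0.0, 0.0, kp=1.0, ki=0.0, kd=0.0, dt=1.0,
                              max_rate=1.0)
    assert rate == 1.0


def test_pid_matches_independent_discrete_recomputation():
    """Track a PID sequence against a brute-force positional recomputation."""
    kp, ki, kd, dt = 2.0, 0.3, 0.1, 1.0
    errors = [0.5, 0.4, 0.2, -0.1, 0.05, 0.3, 0.0, -0.2, 0.6]
    integral = prev = 0.0
    outputs = []
    for e in errors:
        rate, integral = pid_step(e, integral, prev, kp, ki, kd, dt,
                                  max_rate=10.0)
        outputs.append(rate)
        prev = e

    # oracle: textbook positional form with the same clamp rule
    oi = op = 0.0
    for e, got in zip(errors, outputs):
        cand = oi + e * dt
        raw = kp * e + ki * cand + kd * (e - op) / dt
        if 0.0 <= raw <= 10.0:
            oi = cand
            expected = raw
        else:
            expected = min(max(raw, 0.0), 10.0)
        op = e
        assert got == pytest.approx(expected, abs=1e-12)


# -------------------------------------------------------------- closed loop

def make_loop(plant, config=None, transition_prob=0.0, style_noise=0.0):
    plant.transition_prob = transition_prob
    pump = VirtualPeristalticPump(PeristalticPumpSpec(coefficient=8.167e-4),
                                  plant=plant, molarity=0.5,
                                  noise=PERISTALTIC_NOISE["12V"],
                                  rng=plant.rng)
    source = PlantFrameSource(plant, reference_geometry(),
                              reference_style(noise_sd=style_noise))
    return source, reference_calibration(), pump, config or ControlConfig()


def test_zero_generation_plant_needs_no_doses():
    plant = inert_plant(ph=10.60)
    source, cal, pump, config = make_loop(plant)
    result = run_loop(source, cal, pump, plant, config, duration=120)
    assert result.records[-1].cumulative_volume == 0.0
    assert not result.alarm


def test_invalid_only_frames_alarm_at_stale_timeout():
    plant = inert_plant(ph=10.60)
    source, cal, pump, config = make_loop(plant, transition_prob=1.0)
    result = run_loop(source, cal, pump, plant, config, duration=60)
    assert result.alarm
    assert result.alarm_time == config.stale_timeout


def test_log_volume_equals_pump_dispensed_total():
    plant = tempo_reference_plant(seed=6)
    source, cal, pump, config = make_loop(plant)
    result = run_loop(source, cal, pump, plant, config, duration=600)
    assert result.records[-1].cumulative_volume == pytest.approx(
        pump.dispensed_total, rel=1e-12)
    vols = [r.cumulative_volume for r in result.records]
    assert all(b >= a for a, b in zip(vols, vols[1:]))
    times = [r.t for r in result.records]
    assert all(b > a for a, b in zip(times, times[1:]))


def test_reference_loop_holds_band_after_transient():
    """3 h acid-generating run: pH in [10.545, 10.65] after the first 25%."""
    plant = tempo_reference_plant(seed=1)
    source, cal, pump, config = make_loop(plant, style_noise=2.0)
    result = run_loop(source, cal, pump, plant, config, duration=10800)
    tail = [r.ph for r in result.records if r.t > 2700]
    assert max(tail) <= config.setpoint + 0.10
    assert min(tail) >= config.setpoint - 0.005
    assert result.state.unit_volume < config.initial_unit_volume  # adapted


def test_ten_percent_invalid_frames_barely_change_total_volume():
    """Transition frames only delay doses; total titrant tracks the acid."""
    def total(transition_prob):
        plant = tempo_reference_plant(seed=9)
        source, cal, pump, config = make_loop(
            plant, transition_prob=transition_prob)
        return run_loop(source, cal, pump, plant, config,
                        duration=3600).records[-1].cumulative_volume
    clean, noisy = total(0.0), total(0.10)
    assert abs(noisy - clean) / clean < 0.01


def test_resume_offsets_are_respected():
    plant = inert_plant(ph=10.60)
    source, cal, pump, config = make_loop(plant)
    state = ControlState.initial(config)
    result = run_loop(source, cal, pump, plant, config, duration=30,
                      state=state, t_offset=100.0)
    assert result.records[0].t == 100.0


def test_summarize_band_statistics():
    records = [LogRecord(float(t), 10.55 + 0.01 * (t % 3), float(t))
               for t in range(10)]
    s = summarize(records, 10.55)
    assert s["n_records"] == 10
    assert s["ph_min"] == pytest.approx(10.55)
    assert s["ph_max"] == pytest.approx(10.57)
    assert s["band_fraction"] == 1.0
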