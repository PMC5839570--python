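"""pH-stat decision logic: when to dose, how much, and how to adapt.

The rough control rule is deliberately simple and safe: dose one unit
volume iff the latest reading is valid, strictly below the setpoint, and
at least the minimum interval has passed since the previous dose.
Invalid readings (mid-transition frames) never trigger a dose; a long
run of them raises an alarm.

On top sits an adaptation layer mirroring how an operator retunes a
pH-stat as the process slows: after four consecutive dose-eligible
windows pass without a dose, the unit volume is halved (down to a floor)
and the minimum interval doubled (up to a cap); a dose fired while the
pH has sagged more than 0.05 below setpoint reverses one adaptation
step.  All constants are configuration.

A positional PID controller is included as a secondary mode; with a slow
electrode and a fast initial acid burst it is hard to stabilise, which is
why the threshold rule is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

from .ocr import OcrCalibration, Reading, decode_display

__all__ = [
    "Action",
    "ControlConfig",
    "ControlState",
    "LogRecord",
    "RunResult",
    "decide",
    "adapt",
    "manual_mode",
    "pid_step",
    "run_loop",
    "summarize",
]


class Action(Enum):
    DOSE = "dose"
    NONE = "none"
    ALARM = "alarm"


@dataclass(frozen=True)
class ControlConfig:
    """Tunables of the adaptive pH-stat.

    Defaults are the reference operating point for a fast acid-generating
    process held at pH 10.55 with 0.5 M NaOH: 2 ml initial unit volume,
    5 s minimum between doses.
    """

    setpoint: float = 10.55
    initial_unit_volume: float = 2.0     # ml
    min_interval: float = 5.0            # s
    unit_volume_floor: float = 0.5       # ml
    interval_cap: float = 60.0           # s
    stale_timeout: float = 10.0          # s without a valid reading -> ALARM
    log_period: float = 1.0              # s
    adapt_enabled: bool = True
    quiet_windows: int = 4               # dose-free windows before adapting
    deep_excursion: float = 0.05         # pH below setpoint reversing one step

    def __post_init__(self):
        if not (0.0 < self.setpoint < 14.0):
            raise ValueError("setpoint must lie in (0, 14)")
        if self.initial_unit_volume <= 0 or self.unit_volume_floor <= 0:
            raise ValueError("volumes must be positive")
        if self.unit_volume_floor > self.initial_unit_volume:
            raise ValueError("floor cannot exceed the initial unit volume")
        if self.min_interval <= 0:
            raise ValueError("min_interval must be positive")
        if self.interval_cap < self.min_interval:
            raise ValueError("interval_cap must be >= min_interval")


@dataclass
class ControlState:
    """Mutable controller state carried across decision ticks."""

    unit_volume: float
    min_interval: float
    last_dose_time: float = -math.inf
    last_adapt_time: float = -math.inf
    cumulative_volume: float = 0.0
    last_valid_reading: Reading | None = None
    alarm: bool = False

    @classmethod
    def initial(cls, config: ControlConfig) -> "ControlState":
        return cls(unit_volume=config.initial_unit_volume,
                   min_interval=config.min_interval)


@dataclass(frozen=True)
class LogRecord:
    t: float                  # s since run start
    ph: float
    cumulative_volume: float  # ml


def decide(reading: Reading, state: ControlState, config: ControlConfig,
           now: float) -> Action:
    """One decision tick.  Never doses on invalid or above-setpoint readings.

    DOSE iff the reading is valid, strictly below setpoint, and
    ``min_interval`` has elapsed since the last dose.  ALARM iff no valid
    reading has been seen for ``stale_timeout`` seconds.
    """
    if reading.valid:
        state.last_valid_reading = reading
    else:
        last = state.last_valid_reading
        last_t = last.timestamp if last is not None else 0.0
        if now - last_t >= config.stale_timeout:
            state.alarm = True
            return Action.ALARM
        return Action.NONE
    if reading.value >= config.setpoint:
        return Action.NONE
    if now - state.last_dose_time < state.min_interval:
        return Action.NONE
    return Action.DOSE


def adapt(state: ControlState, config: ControlConfig, now: float,
          dosed: bool = False, reading: Reading | None = None) -> ControlState:
    """Adaptation step, called once per decision tick after acting.

    Quiet spell of ``quiet_windows`` x ``min_interval`` with no dose →
    halve the unit volume (floor) and double the interval (cap).  A dose
    fired while the pH sits more than ``deep_excursion`` below setpoint
    reverses one adaptation step (the process sped up again).
    """
    if not config.adapt_enabled:
        return state
    if dosed:
        if (reading is not None and reading.valid
                and reading.value < config.setpoint - config.deep_excursion):
            state.unit_volume = min(config.initial_unit_volume,
                                    state.unit_volume * 2.0)
            state.min_interval = max(config.min_interval,
                                     state.min_interval / 2.0)
        state.last_adapt_time = now
        return state
    quiet_since = max(state.last_dose_time, state.last_adapt_time)
    if now - quiet_since >= config.quiet_windows * state.min_interval:
        state.unit_volume = max(config.unit_volume_floor,
                                state.unit_volume / 2.0)
        state.min_interval = min(config.interval_cap,
                                 state.min_interval * 2.0)
        state.last_adapt_time = now
    return state


def pid_step(error: float, integral: float, previous_error: float,
             kp: float, ki: float, kd: float, dt: float,
             max_rate: float = math.inf) -> tuple[float, float]:
    """Positional PID with output clamped to [0, max_rate] and anti-windup.

    Returns ``(dose_rate_ml_per_s, new_integral)``; the integral is
    frozen while the output saturates.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    candidate_integral = integral + error * dt
    derivative = (error - previous_error) / dt
    raw = kp * error + ki * candidate_integral + kd * derivative
    if 0.0 <= raw <= max_rate:
        return raw, candidate_integral
    return min(max(raw, 0.0), max_rate), integral


def manual_mode(events: Sequence[tuple[str, float]], pump) -> list[tuple[float, float]]:
    """Replay start/stop button events against a pump.

    ``events`` is a time-ordered list of ("start"|"stop", t_seconds); the
    pump runs continuously between a start and the following stop.  A
    stop without a start is a no-op; a trailing start is ignored.
    Returns ``[(t_start, delivered_ml), ...]``.
    """
    doses = []
    started: float | None = None
    for cmd, t in events:
        if cmd == "start":
            if started is None:
                started = t
        elif cmd == "stop":
            if started is not None:
                elapsed_ms = (t - started) * 1000.0
                delivered = pump.run_for(elapsed_ms) if elapsed_ms > 0 else 0.0
                doses.append((started, delivered))
                started = None
        else:
            raise ValueError(f"unknown manual command {cmd!r}")
    return doses


@dataclass
class RunResult:
    """Outcome of a closed-loop run."""

    records: list[LogRecord]
    state: ControlState
    alarm: bool = False
    alarm_time: float | None = None

    def summary(self, setpoint: float, band: float = 0.10) -> dict:
        return summarize(self.records, setpoint, band)


def summarize(records: Sequence[LogRecord], setpoint: float,
              band: float = 0.10) -> dict:
    """Run summary: total volume, final pH, and band statistics."""
    if not records:
        return {"n_records": 0, "total_volume_ml": 0.0}
    phs = [r.ph for r in records if not math.isnan(r.ph)]
    in_band = [p for p in phs if setpoint <= p <= setpoint + band]
    return {
        "n_records": len(records),
        "total_volume_ml": records[-1].cumulative_volume,
        "final_ph": records[-1].ph,
        "ph_min": min(phs) if phs else float("nan"),
        "ph_max": max(phs) if phs else float("nan"),
        "band_fraction": len(in_band) / len(phs) if phs else 0.0,
    }


def run_loop(frame_source, cal: OcrCalibration, pump, plant,
             config: ControlConfig, duration: float,
             state: ControlState | None = None,
             t_offset: float = 0.0,
             tick: float = 1.0) -> RunResult:
    """Closed loop: acquire frame → decode → decide → dose → adapt → log.

    ``plant`` is stepped ``tick`` seconds per iteration with whatever the
    pump delivered that tick (pass ``plant=None`` when the frame source
    and pump face real hardware and time passes on its own).  An ALARM
    terminates the loop with the log flagged.  ``state``/``t_offset``
    allow resuming a previous run from its log.
    """
    if state is None:
        state = ControlState.initial(config)
    records: list[LogRecord] = []
    n_ticks = int(round(duration / tick))
    next_log = 0.0
    alarm_time = None
    for k in range(n_ticks):
        now = k * tick
        frame, _ = frame_source.next_frame()
        reading = decode_display(frame, cal, timestamp=now)
        if reading.valid:
            reading = replace(reading, timestamp=now)
        action = decide(reading, state, config, now)
        dosed = False
        if action is Action.DOSE:
            delivered = pump.dose(state.unit_volume)
            state.cumulative_volume += delivered
            state.last_dose_time = now
            dosed = True
        adapt(state, config, now, dosed=dosed, reading=reading)
        if plant is not None:
            pending = pump.take_pending() if hasattr(pump, "take_pending") else 0.0
            molarity = getattr(pump, "molarity", 0.0)
            plant.step(tick, added_ml=pending, molarity=molarity)
        if now >= next_log - 1e-9:
            last = state.last_valid_reading
            ph = last.value if last is not None else float("nan")
            records.append(LogRecord(t_offset + now, ph,
                                     state.cumulative_volume))
            next_log += config.log_period
        if action is Action.ALARM:
            alarm_time = now
            break
    return RunResult(records, state, alarm=state.alarm, alarm_time=alarm_time)
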