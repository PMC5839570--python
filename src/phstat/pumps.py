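"""Pump dosing models, calibration fitting, and the module wire protocol.

Two dosing mechanisms are modelled.  A syringe pump drives a plunger
through a leadscrew from a stepper motor, so delivered volume is
proportional to motor steps: with a NEMA 17 (200 steps/rev) and a 0.8 mm
pitch leadscrew the plunger advances 0.004 mm/step, i.e. ~0.0013 ml/step
through a nominal 20 ml syringe bore.  A peristaltic pump with a
permanent-magnet motor is time-calibrated: delivered volume is
(run time − dead time) × a ml/ms coefficient fitted from repeated test
doses.

Pump modules identify themselves over a line-oriented ASCII protocol
(IDENTIFY/IDENTITY/DOSE/...); the transport is abstract so the same
client code drives an in-memory virtual pump or real hardware.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from .exceptions import CapacityError, ProtocolError, UnreliableDoseWarning

__all__ = [
    "SyringePumpSpec",
    "PeristalticPumpSpec",
    "ModuleIdentity",
    "CalibrationMeasurement",
    "CalibrationFit",
    "mm_per_step",
    "ml_per_step",
    "volume_to_steps",
    "volume_to_runtime",
    "runtime_to_volume",
    "steps_to_volume",
    "fit_calibration",
    "SyringeDoser",
    "Message",
    "protocol_encode",
    "protocol_decode",
    "Transport",
    "LoopbackTransport",
    "PumpClient",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class SyringePumpSpec:
    """Leadscrew syringe pump: geometry fully determines ml/step.

    ``plunger_position`` counts steps from the fully-drawn position, so
    dispensed volume so far is ``plunger_position * ml_per_step``.
    """

    syringe_inner_diameter: float        # mm
    syringe_capacity: float              # ml
    steps_per_rev: int = 200             # NEMA 17 full-step
    lead: float = 0.8                    # mm advanced per revolution
    plunger_position: int = 0            # steps from fully drawn

    def __post_init__(self):
        if self.steps_per_rev <= 0:
            raise ValueError("steps_per_rev must be positive")
        if self.lead <= 0:
            raise ValueError("lead must be positive")
        if self.syringe_inner_diameter <= 0:
            raise ValueError("syringe_inner_diameter must be positive")
        if self.syringe_capacity <= 0:
            raise ValueError("syringe_capacity must be positive")
        if self.plunger_position < 0:
            raise ValueError("plunger_position must be >= 0")


@dataclass
class PeristalticPumpSpec:
    """Time-calibrated peristaltic pump.

    ``coefficient`` is the fitted steady-state delivery rate in ml/ms;
    ``dead_time`` the unproductive start-up of the permanent-magnet motor.
    Doses below ``min_reliable_dose`` are delivered but flagged: short
    runs are dominated by the unstable start. Defaults model a 12 V
    supply; a 9 V supply has a longer unstable start (dead_time 40 ms,
    min_reliable_dose 1.5 ml).
    """

    coefficient: float                   # ml per ms
    dead_time: float = 0.0               # ms
    min_reliable_dose: float = 0.5       # ml
    supply_voltage_tag: str = "12V"

    def __post_init__(self):
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")


#: peristaltic defaults per supply voltage (dead_time ms, min_reliable_dose ml)
PERISTALTIC_PROFILES = {"12V": (0.0, 0.5), "9V": (40.0, 1.5)}


def peristaltic_spec(coefficient: float, supply: str = "12V") -> PeristalticPumpSpec:
    """Spec with voltage-profile defaults filled in."""
    dead, min_dose = PERISTALTIC_PROFILES[supply]
    return PeristalticPumpSpec(coefficient, dead, min_dose, supply)


@dataclass
class ModuleIdentity:
    """What a pump module announces on connection."""

    name: str
    description: str
    reagent: str
    pump_type: str                       # "peristaltic" | "syringe"
    calibration: SyringePumpSpec | PeristalticPumpSpec

    def __post_init__(self):
        expected = {"syringe": SyringePumpSpec,
                    "peristaltic": PeristalticPumpSpec}
        if self.pump_type not in expected:
            raise ValueError(f"unknown pump_type {self.pump_type!r}")
        if not isinstance(self.calibration, expected[self.pump_type]):
            raise ValueError("calibration payload inconsistent with pump_type")


# --------------------------------------------------------------------------
# volume <-> actuation math
# --------------------------------------------------------------------------

def mm_per_step(spec: SyringePumpSpec) -> float:
    """Plunger advance per motor step (lead / steps_per_rev)."""
    return spec.lead / spec.steps_per_rev


def ml_per_step(spec: SyringePumpSpec) -> float:
    """Volume per motor step: bore cross-section x advance (1 ml = 1000 mm^3)."""
    area_mm2 = math.pi * (spec.syringe_inner_diameter / 2.0) ** 2
    return area_mm2 * mm_per_step(spec) / 1000.0


def volume_to_steps(spec: SyringePumpSpec, volume: float,
                    carry: float = 0.0) -> tuple[int, float]:
    """Motor steps for ``volume`` ml, with sub-step residual carried forward.

    Returns ``(steps, new_carry)``; accumulating ``carry`` across a dosing
    sequence keeps the rounding error bounded by one step's volume instead
    of drifting.  Raises :class:`CapacityError` when the syringe cannot
    hold the dose.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    per = ml_per_step(spec)
    exact = (volume + carry) / per
    steps = int(round(exact))
    remaining = spec.syringe_capacity - spec.plunger_position * per
    if steps * per > remaining + 0.5 * per:
        raise CapacityError(
            f"dose of {volume} ml exceeds remaining {remaining:.3f} ml")
    return steps, (exact - steps) * per


def steps_to_volume(spec: SyringePumpSpec, steps: int) -> float:
    return steps * ml_per_step(spec)


def volume_to_runtime(spec: PeristalticPumpSpec, volume: float) -> float:
    """Motor run time (ms) delivering ``volume`` ml at steady rate.

    Warns (:class:`UnreliableDoseWarning`) below ``min_reliable_dose`` —
    the dose is still produced.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if volume < spec.min_reliable_dose:
        warnings.warn(
            f"{volume} ml is below the reliable minimum "
            f"({spec.min_reliable_dose} ml at {spec.supply_voltage_tag})",
            UnreliableDoseWarning, stacklevel=2)
    return spec.dead_time + volume / spec.coefficient


def runtime_to_volume(spec: PeristalticPumpSpec, runtime_ms: float) -> float:
    """Volume delivered by running for ``runtime_ms`` (zero within dead time)."""
    return max(0.0, (runtime_ms - spec.dead_time)) * spec.coefficient


class SyringeDoser:
    """Stateful wrapper executing doses against a syringe spec.

    Tracks the plunger, carries sub-step residuals forward, and enforces
    capacity.  Volume accounting is exact: total dispensed equals
    executed steps x ml/step.
    """

    def __init__(self, spec: SyringePumpSpec):
        self.spec = spec
        self.carry = 0.0

    @property
    def dispensed_ml(self) -> float:
        return self.spec.plunger_position * ml_per_step(self.spec)

    @property
    def remaining_ml(self) -> float:
        return self.spec.syringe_capacity - self.dispensed_ml

    def dose(self, volume: float) -> int:
        """Execute a dose; returns the motor steps actually commanded."""
        steps, self.carry = volume_to_steps(self.spec, volume, self.carry)
        self.spec.plunger_position += steps
        return steps


# --------------------------------------------------------------------------
# calibration fitting
# --------------------------------------------------------------------------

@dataclass
class CalibrationMeasurement:
    """One calibration dose: actuation amount and the volume it produced."""

    run_time: float                      # ms (peristaltic) or steps (syringe)
    measured_volume: float               # ml

    def __post_init__(self):
        if self.run_time <= 0 or self.measured_volume <= 0:
            raise ValueError("run_time and measured_volume must be positive")


@dataclass
class CalibrationFit:
    coefficient: float                   # ml per ms (or ml per step)
    n: int
    residual_cv: float                   # spread of per-dose ratios / coefficient

    def as_ml_per_min(self) -> float:
        """Convenience for ml/ms coefficients."""
        return self.coefficient * 60000.0


def fit_calibration(measurements: Sequence[CalibrationMeasurement]) -> CalibrationFit:
    """Pooled ratio-of-sums calibration coefficient.

    The pump is calibrated by repeating a fixed actuation (e.g. fifty
    500 ms runs) and measuring total delivered volume; the coefficient is
    total volume / total run time.  The ratio-of-sums estimator matches
    that pooled procedure and is robust to per-dose noise.  The
    per-measurement ratio spread is reported as a coefficient of
    variation for diagnostics.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("at least one measurement required")
    total_v = sum(m.measured_volume for m in ms)
    total_t = sum(m.run_time for m in ms)
    coef = total_v / total_t
    if len(ms) > 1:
        ratios = [m.measured_volume / m.run_time for m in ms]
        mean = sum(ratios) / len(ratios)
        var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
        cv = math.sqrt(var) / coef
    else:
        cv = 0.0
    return CalibrationFit(coef, len(ms), cv)


# --------------------------------------------------------------------------
# module protocol
# --------------------------------------------------------------------------

_SPEC_CODECS = {"syringe": SyringePumpSpec, "peristaltic": PeristalticPumpSpec}

#: verb -> allowed payload keys
_GRAMMAR = {
    "IDENTIFY": set(),
    "IDENTITY": {"name", "description", "reagent", "pump_type", "calibration"},
    "DOSE": {"amount", "unit", "rate"},
    "STOP": set(),
    "GET_CAL": set(),
    "SET_CAL": {"pump_type", "calibration"},
    "ACK": {"detail"},
    "ERROR": {"text"},
}


@dataclass(frozen=True)
class Message:
    """A protocol message: a verb plus a JSON-serialisable payload."""

    verb: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.verb not in _GRAMMAR:
            raise ProtocolError(f"unknown verb {self.verb!r}")
        extra = set(self.payload) - _GRAMMAR[self.verb]
        if extra:
            raise ProtocolError(f"{self.verb} does not accept {sorted(extra)}")


def _encode_payload(payload: dict) -> dict:
    out = {}
    for k, v in payload.items():
        if isinstance(v, (SyringePumpSpec, PeristalticPumpSpec)):
            out[k] = asdict(v)
        elif isinstance(v, ModuleIdentity):
            out[k] = asdict(v)
        else:
            out[k] = v
    return out


def protocol_encode(message: Message) -> str:
    """One newline-terminated ASCII line: ``VERB {json payload}``."""
    if message.payload:
        body = json.dumps(_encode_payload(message.payload),
                          sort_keys=True, separators=(",", ":"))
        return f"{message.verb} {body}\n"
    return f"{message.verb}\n"


def protocol_decode(line: str) -> Message:
    """Inverse of :func:`protocol_encode`; structured specs are revived."""
    text = line.strip()
    if not text:
        raise ProtocolError("empty line", line)
    verb, _, rest = text.partition(" ")
    if verb not in _GRAMMAR:
        raise ProtocolError(f"unknown verb {verb!r}", line)
    payload: dict = {}
    if rest:
        try:
            payload = json.loads(rest)
        except json.JSONDecodeError as e:
            raise ProtocolError(f"bad payload: {e}", line) from None
        if not isinstance(payload, dict):
            raise ProtocolError("payload must be a JSON object", line)
    if "calibration" in payload and "pump_type" in payload:
        cls = _SPEC_CODECS.get(payload["pump_type"])
        if cls is None:
            raise ProtocolError(f"unknown pump_type {payload['pump_type']!r}", line)
        try:
            payload["calibration"] = cls(**payload["calibration"])
        except (TypeError, ValueError) as e:
            raise ProtocolError(f"bad calibration payload: {e}", line) from None
    try:
        return Message(verb, payload)
    except ProtocolError:
        raise
    except Exception as e:  # payload shape violations
        raise ProtocolError(str(e), line) from None


# --------------------------------------------------------------------------
# transport
# --------------------------------------------------------------------------

class Transport:
    """Line transport contract: ``write_line`` / ``read_line`` with timeout."""

    def write_line(self, line: str) -> None:
        raise NotImplementedError

    def read_line(self, timeout: float = 1.0) -> str:
        raise NotImplementedError


class LoopbackTransport(Transport):
    """In-memory request/response transport bound to a server callable.

    The server receives each written line and returns the response
    line(s); this stands in for the USB serial link to a module.
    """

    def __init__(self, server):
        self._server = server
        self._inbox: list[str] = []

    def write_line(self, line: str) -> None:
        reply = self._server(line)
        if reply is not None:
            if isinstance(reply, str):
                reply = [reply]
            self._inbox.extend(reply)

    def read_line(self, timeout: float = 1.0) -> str:
        if not self._inbox:
            raise TimeoutError("no line available")
        return self._inbox.pop(0)


class PumpClient:
    """Drives one pump module over a transport using the line protocol."""

    def __init__(self, transport: Transport):
        self.transport = transport
        self.identity: ModuleIdentity | None = None

    def _exchange(self, message: Message) -> Message:
        self.transport.write_line(protocol_encode(message))
        reply = protocol_decode(self.transport.read_line())
        if reply.verb == "ERROR":
            raise ProtocolError(reply.payload.get("text", "module error"))
        return reply

    def identify(self) -> ModuleIdentity:
        reply = self._exchange(Message("IDENTIFY"))
        if reply.verb != "IDENTITY":
            raise ProtocolError(f"expected IDENTITY, got {reply.verb}")
        p = reply.payload
        self.identity = ModuleIdentity(p["name"], p["description"],
                                       p["reagent"], p["pump_type"],
                                       p["calibration"])
        return self.identity

    def get_calibration(self):
        reply = self._exchange(Message("GET_CAL"))
        return reply.payload["calibration"]

    def set_calibration(self, spec) -> None:
        pump_type = ("syringe" if isinstance(spec, SyringePumpSpec)
                     else "peristaltic")
        self._exchange(Message("SET_CAL", {"pump_type": pump_type,
                                           "calibration": spec}))

    def dose(self, volume_ml: float) -> float:
        """Request a dose by volume; returns the module's delivered ml."""
        if self.identity is None:
            self.identify()
        if self.identity.pump_type == "peristaltic":
            spec = self.identity.calibration
            amount, unit = volume_to_runtime(spec, volume_ml), "ms"
        else:
            amount, unit = volume_ml, "ml"
        reply = self._exchange(Message("DOSE", {"amount": amount,
                                                "unit": unit, "rate": None}))
        return float(reply.payload.get("detail", 0.0))

    def stop(self) -> None:
        self._exchange(Message("STOP"))
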