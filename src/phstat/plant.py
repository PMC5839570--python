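"""Virtual chemistry: the ground-truth plant the control loop runs against.

The plant is a stirred strong-electrolyte solution.  Its true pH follows
from the charge balance [H+]^2 + (C_b - C_a)[H+] - Kw = 0, where C_a and
C_b are the net strong-acid and strong-base concentrations — exact,
closed-form, and valid through the equivalence point.  An acid-generating
process models a TEMPO-mediated oxidation consuming hydroxide: a fast
initial phase decaying exponentially into a slow tail,
r(t) = r_fast * exp(-t / tau_fast) + r_slow (mol acid / s), integrated
exactly over each step.  The measured pH relaxes toward the true pH with
a first-order electrode lag and carries Gaussian reading noise; frames of
the measured value are emitted through the display renderer, occasionally
corrupted to mimic mid-transition captures.

Virtual pumps deliver requested doses with actuation noise: syringe doses
have a ~1% multiplicative error; peristaltic doses are relatively
noisier the smaller they are (the permanent-magnet motor's unstable
start), more so on a 9 V supply than on 12 V.

All randomness draws from a single seeded generator per simulation, so a
run is reproducible bit-for-bit; with noise, lag and frame corruption
disabled the whole loop is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import ocr
from .exceptions import CapacityError
from .pumps import (ModuleIdentity, PeristalticPumpSpec, SyringePumpSpec,
                    SyringeDoser, ml_per_step, peristaltic_spec,
                    runtime_to_volume, volume_to_runtime)

__all__ = [
    "ph_strong",
    "TempoKinetics",
    "Plant",
    "ActuationNoise",
    "VirtualSyringePump",
    "VirtualPeristalticPump",
    "PlantFrameSource",
    "tempo_reference_plant",
    "reference_geometry",
    "reference_style",
    "reference_calibration",
    "SCENARIOS",
    "build_scenario",
]


def ph_strong(c_acid: float, c_base: float, kw: float = 1.0e-14) -> float:
    """pH of a strong acid/strong base mixture from the exact charge balance.

    Solves [H]^2 + (C_b - C_a)[H] - Kw = 0 for the positive root using the
    numerically stable quadratic form (no cancellation on either side of
    equivalence).
    """
    if c_acid < 0 or c_base < 0:
        raise ValueError("concentrations must be non-negative")
    if kw <= 0:
        raise ValueError("Kw must be positive")
    b = c_base - c_acid
    disc = math.sqrt(b * b + 4.0 * kw)
    if b <= 0:
        h = (-b + disc) / 2.0
    else:
        # avoid cancellation when base dominates: [H] = Kw / [OH]
        oh = (b + disc) / 2.0
        h = kw / oh
    return -math.log10(h)


@dataclass(frozen=True)
class TempoKinetics:
    """Two-regime acid generation: fast exponential burst plus slow tail.

    Defaults emulate a 2.5 L TEMPO-mediated cellulose oxidation held with
    0.5 M NaOH: early demand ≈ 1.2 ml of titrant per 5 s decaying over
    ~10 min into a tail demanding ≈ 0.5 ml per 250 s, ≈ 165 ml in total
    over 3 h.
    """

    r_fast: float = 1.2e-4      # mol acid / s at t = 0
    tau_fast: float = 600.0     # s
    r_slow: float = 1.0e-6      # mol acid / s, persistent tail
    duration: float = 10800.0   # s; generation stops afterwards

    def rate(self, t: float) -> float:
        if t >= self.duration:
            return 0.0
        return self.r_fast * math.exp(-t / self.tau_fast) + self.r_slow

    def integral(self, t0: float, t1: float) -> float:
        """Exact moles of acid generated over [t0, t1]."""
        t0 = min(t0, self.duration)
        t1 = min(t1, self.duration)
        if t1 <= t0:
            return 0.0
        fast = self.r_fast * self.tau_fast * (
            math.exp(-t0 / self.tau_fast) - math.exp(-t1 / self.tau_fast))
        return fast + self.r_slow * (t1 - t0)


@dataclass
class Plant:
    """Stirred-solution state with electrode lag and seeded reading noise."""

    volume_l: float
    acid_mol: float = 0.0
    base_mol: float = 0.0
    kw: float = 1.0e-14
    generation: TempoKinetics | None = None
    electrode_tau: float = 20.0          # s; 0 disables the lag
    noise_sd: float = 0.0                # pH units on each reading
    transition_prob: float = 0.0         # corrupted-frame probability
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng())
    t: float = 0.0

    def __post_init__(self):
        if self.volume_l <= 0:
            raise ValueError("volume must be positive")
        if self.acid_mol < 0 or self.base_mol < 0:
            raise ValueError("moles must be non-negative")
        self._ph_lagged = self.true_ph

    @property
    def true_ph(self) -> float:
        return ph_strong(self.acid_mol / self.volume_l,
                         self.base_mol / self.volume_l, self.kw)

    @property
    def measured_ph(self) -> float:
        """Electrode output before reading noise (lagged true pH)."""
        return self._ph_lagged

    def step(self, dt: float, added_ml: float = 0.0,
             molarity: float = 0.0) -> None:
        """Advance ``dt`` seconds, optionally adding titrant first.

        Added base and generated acid enter the balance, the volume grows
        by the added titrant, and the electrode relaxes toward the new
        true pH with time constant ``electrode_tau``.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if added_ml < 0:
            raise ValueError("added volume must be non-negative")
        if added_ml:
            self.base_mol += added_ml / 1000.0 * molarity
            self.volume_l += added_ml / 1000.0
        if self.generation is not None:
            self.acid_mol += self.generation.integral(self.t, self.t + dt)
        self.t += dt
        target = self.true_ph
        if self.electrode_tau > 0:
            alpha = 1.0 - math.exp(-dt / self.electrode_tau)
            self._ph_lagged += alpha * (target - self._ph_lagged)
        else:
            self._ph_lagged = target

    def read_ph(self) -> float:
        """One electrode reading: lagged pH plus seeded Gaussian noise."""
        if self.noise_sd > 0:
            return self._ph_lagged + self.rng.normal(0.0, self.noise_sd)
        return self._ph_lagged

    def emit_frame(self, geometry: ocr.SegmentGeometry,
                   style: ocr.RenderStyle = ocr.RenderStyle()) -> np.ndarray:
        """Render a display frame of the current reading.

        With probability ``transition_prob`` one digit's pattern is
        replaced by a non-decodable one, mimicking a frame captured while
        the display was changing.
        """
        value = round(self.read_ph(), geometry.fractional_digits)
        value = min(max(value, 0.0),
                    10 ** geometry.decimal_index - geometry.resolution)
        if self.transition_prob > 0 and self.rng.random() < self.transition_prob:
            patterns = [ocr.GLYPH_SEGMENTS[g]
                        for g in ocr.glyphs_for_value(value, geometry)]
            idx = int(self.rng.integers(geometry.n_digits))
            patterns[idx] = _INVALID_PATTERNS[
                int(self.rng.integers(len(_INVALID_PATTERNS)))]
            return ocr.render_patterns(patterns, geometry, style, self.rng)
        return ocr.render_display(value, geometry, style, self.rng)


def _build_invalid_patterns():
    out = []
    for m in range(128):
        pat = frozenset(s for i, s in enumerate(ocr.SEGMENTS) if (m >> i) & 1)
        if ocr.decode_digit(pat) == ocr.INVALID:
            out.append(pat)
    return out


#: every 7-bit pattern that decodes to INVALID (116 of 128)
_INVALID_PATTERNS = _build_invalid_patterns()


# --------------------------------------------------------------------------
# virtual pumps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ActuationNoise:
    """Multiplicative dose noise sigma = sigma0 * (1 + v_ref / volume).

    The relative error grows as doses shrink, reproducing the ordering
    seen on cheap peristaltic pumps (short runs dominated by the unstable
    motor start); ``v_ref`` sets how quickly small doses degrade.
    """

    sigma0: float = 0.01
    v_ref: float = 0.0

    def sigma(self, volume_ml: float) -> float:
        if volume_ml <= 0:
            return 0.0
        return self.sigma0 * (1.0 + self.v_ref / volume_ml)


#: qualitative supply-voltage noise profiles (9 V markedly worse)
PERISTALTIC_NOISE = {"12V": ActuationNoise(0.01, 0.2),
                     "9V": ActuationNoise(0.02, 1.0)}


class VirtualSyringePump:
    """Syringe pump attached to a plant: quantised steps, ~1% dose noise."""

    def __init__(self, spec: SyringePumpSpec, plant: Plant | None = None,
                 molarity: float = 0.0, noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None):
        self.doser = SyringeDoser(spec)
        self.plant = plant
        self.molarity = molarity
        self.noise_sd = noise_sd
        self.rng = rng if rng is not None else (
            plant.rng if plant is not None else np.random.default_rng())
        self.dispensed_total = 0.0
        self._pending = 0.0

    def dose(self, volume_ml: float) -> float:
        steps = self.doser.dose(volume_ml)
        delivered = steps * ml_per_step(self.doser.spec)
        if self.noise_sd > 0:
            delivered *= 1.0 + self.rng.normal(0.0, self.noise_sd)
        delivered = max(0.0, delivered)
        self.dispensed_total += delivered
        self._pending += delivered
        return delivered

    def take_pending(self) -> float:
        """Volume dosed since the last plant step (consumed by the loop)."""
        v, self._pending = self._pending, 0.0
        return v


class VirtualPeristalticPump:
    """Time-calibrated pump with volume-dependent actuation noise."""

    def __init__(self, spec: PeristalticPumpSpec, plant: Plant | None = None,
                 molarity: float = 0.0, noise: ActuationNoise | None = None,
                 rng: np.random.Generator | None = None):
        self.spec = spec
        self.plant = plant
        self.molarity = molarity
        self.noise = noise if noise is not None else ActuationNoise(0.0, 0.0)
        self.rng = rng if rng is not None else (
            plant.rng if plant is not None else np.random.default_rng())
        self.dispensed_total = 0.0
        self._pending = 0.0

    def _deliver(self, runtime_ms: float) -> float:
        nominal = runtime_to_volume(self.spec, runtime_ms)
        if nominal <= 0:
            return 0.0
        sigma = self.noise.sigma(nominal)
        if sigma > 0:
            nominal *= 1.0 + self.rng.normal(0.0, sigma)
        delivered = max(0.0, nominal)
        self.dispensed_total += delivered
        self._pending += delivered
        return delivered

    def dose(self, volume_ml: float) -> float:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # reliability warning is advisory here
            runtime = volume_to_runtime(self.spec, volume_ml)
        return self._deliver(runtime)

    def run_for(self, runtime_ms: float) -> float:
        """Manual-mode primitive: run the motor for a given time."""
        return self._deliver(runtime_ms)

    def take_pending(self) -> float:
        v, self._pending = self._pending, 0.0
        return v


class VirtualPumpServer:
    """Module-side protocol endpoint wrapping a virtual pump.

    Emulates the microcontroller firmware: answers IDENTIFY with the
    module identity (persistent calibration included, as a module's
    EEPROM would hold it), executes DOSE commands against the virtual
    pump, and serves GET_CAL/SET_CAL.  Plug into
    :class:`phstat.pumps.LoopbackTransport` to drive it from a
    :class:`phstat.pumps.PumpClient`.
    """

    def __init__(self, pump, identity: "ModuleIdentity"):
        self.pump = pump
        self.identity = identity

    def __call__(self, line: str) -> str:
        from .pumps import Message, protocol_decode, protocol_encode
        try:
            msg = protocol_decode(line)
        except Exception as e:
            return protocol_encode(Message("ERROR", {"text": str(e)}))
        try:
            if msg.verb == "IDENTIFY":
                ident = self.identity
                return protocol_encode(Message("IDENTITY", {
                    "name": ident.name, "description": ident.description,
                    "reagent": ident.reagent, "pump_type": ident.pump_type,
                    "calibration": ident.calibration}))
            if msg.verb == "GET_CAL":
                ident = self.identity
                return protocol_encode(Message("IDENTITY", {
                    "name": ident.name, "description": ident.description,
                    "reagent": ident.reagent, "pump_type": ident.pump_type,
                    "calibration": ident.calibration}))
            if msg.verb == "SET_CAL":
                self.identity.calibration = msg.payload["calibration"]
                return protocol_encode(Message("ACK", {"detail": "cal"}))
            if msg.verb == "DOSE":
                amount = msg.payload["amount"]
                if msg.payload.get("unit") == "ms":
                    delivered = self.pump.run_for(amount)
                else:
                    delivered = self.pump.dose(amount)
                return protocol_encode(Message("ACK", {"detail": delivered}))
            if msg.verb == "STOP":
                return protocol_encode(Message("ACK", {"detail": "stopped"}))
            return protocol_encode(Message("ERROR",
                                           {"text": f"unexpected {msg.verb}"}))
        except CapacityError as e:
            return protocol_encode(Message("ERROR", {"text": str(e)}))
        except Exception as e:
            return protocol_encode(Message("ERROR", {"text": str(e)}))


class PlantFrameSource:
    """Frame-source contract (``next_frame() -> (frame, t)``) over a plant."""

    def __init__(self, plant: Plant, geometry: ocr.SegmentGeometry,
                 style: ocr.RenderStyle = ocr.RenderStyle()):
        self.plant = plant
        self.geometry = geometry
        self.style = style

    def next_frame(self) -> tuple[np.ndarray, float]:
        return self.plant.emit_frame(self.geometry, self.style), self.plant.t


# --------------------------------------------------------------------------
# reference scenarios
# --------------------------------------------------------------------------

def reference_geometry() -> ocr.SegmentGeometry:
    """5-digit display, decimal after the 2nd digit (pH to 0.001)."""
    return ocr.SegmentGeometry(anchor_row=4, anchor_col=4, digit_width=12,
                               digit_height=20, digit_pitch=17,
                               n_digits=5, decimal_index=2)


def reference_style(noise_sd: float = 0.0) -> ocr.RenderStyle:
    return ocr.RenderStyle(on_intensity=230, off_intensity=30,
                           background=10, noise_sd=noise_sd)


def reference_calibration() -> ocr.OcrCalibration:
    return ocr.OcrCalibration(threshold=128, geometry=reference_geometry())


def _base_for_ph(ph: float, volume_l: float, kw: float = 1.0e-14) -> float:
    """Strong-base moles giving ``ph`` in pure water of ``volume_l``."""
    h = 10.0 ** -ph
    return (kw / h - h) * volume_l


def tempo_reference_plant(seed: int | np.random.Generator = 0,
                          noise_sd: float = 0.001,
                          electrode_tau: float = 20.0,
                          transition_prob: float = 0.0) -> Plant:
    """The reference acid-generating scenario: 2.5 L held at pH 10.55.

    Starts at the setpoint with the default two-regime kinetics; dosing
    uses 0.5 M NaOH.  Reading noise defaults to one display quantum.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return Plant(volume_l=2.5, acid_mol=0.0,
                 base_mol=_base_for_ph(10.55, 2.5),
                 generation=TempoKinetics(),
                 electrode_tau=electrode_tau, noise_sd=noise_sd,
                 transition_prob=transition_prob, rng=rng)


def hcl_analyte_plant(analyte_ml: float = 10.0, analyte_molar: float = 0.1,
                      seed: int | np.random.Generator = 0,
                      electrode_tau: float = 0.0,
                      noise_sd: float = 0.0) -> Plant:
    """Titration analyte: strong acid in water, no generation."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return Plant(volume_l=analyte_ml / 1000.0,
                 acid_mol=analyte_ml / 1000.0 * analyte_molar,
                 generation=None, electrode_tau=electrode_tau,
                 noise_sd=noise_sd, rng=rng)


def inert_plant(ph: float = 10.55, volume_l: float = 2.5,
                seed: int | np.random.Generator = 0) -> Plant:
    """No acid generation: the controller should go quiet immediately."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    base = _base_for_ph(ph, volume_l)
    return Plant(volume_l=volume_l, acid_mol=max(0.0, -base),
                 base_mol=max(0.0, base), generation=None,
                 electrode_tau=0.0, noise_sd=0.0, rng=rng)


SCENARIOS = {
    "tempo_default": tempo_reference_plant,
    "inert": inert_plant,
    "hcl_titration": hcl_analyte_plant,
}


def build_scenario(name: str, seed: int = 0, **overrides) -> Plant:
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"choose from {sorted(SCENARIOS)}")
    return SCENARIOS[name](seed=seed, **overrides)
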