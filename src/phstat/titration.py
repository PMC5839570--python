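"""Stability-gated potentiometric titration and equivalence-point analysis.

A titration adds predefined titrant increments, waiting before each
addition until the pH has settled: the reading now and the reading one
stability window ago must agree within epsilon.  The recorded curve is
(cumulative titrant volume, pH).  The equivalence point is estimated by
the first-derivative method: the maximum of dpH/dV on the (possibly
uneven) volume grid, refined by parabolic interpolation through the peak
and its neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .exceptions import TitrationTimeout

__all__ = [
    "TitrationConfig",
    "TitrationCurve",
    "EquivalenceResult",
    "titrate",
    "equivalence_point",
]


@dataclass(frozen=True)
class TitrationConfig:
    """Increment schedule and stability gate.

    ``increment_schedule`` is a list of ``(volume_ml, count)`` stages —
    coarse steps early, finer near the expected equivalence if desired.
    Stability compares the endpoints of a ``stability_window`` (seconds)
    against ``stability_epsilon`` (pH); the epsilon default of 0.005 is
    five display quanta, comfortably above read noise on a stable meter.
    """

    increment_schedule: Sequence[tuple[float, int]]
    stability_window: float = 5.0
    stability_epsilon: float = 0.005
    max_volume: float = math.inf
    stability_timeout: float = 600.0     # s to wait for stability before failing

    def __post_init__(self):
        for vol, count in self.increment_schedule:
            if vol <= 0 or count < 0:
                raise ValueError("increments must be positive, counts >= 0")
        if self.stability_window <= 0:
            raise ValueError("stability_window must be positive")
        if self.stability_epsilon < 0.001:
            raise ValueError("epsilon below display resolution (0.001)")

    @classmethod
    def uniform(cls, increment_ml: float, count: int, **kw) -> "TitrationConfig":
        return cls([(increment_ml, count)], **kw)

    def increments(self):
        for vol, count in self.increment_schedule:
            for _ in range(count):
                yield vol


@dataclass
class TitrationCurve:
    """Ordered (cumulative_volume_ml, pH) points; volumes strictly increase."""

    points: list[tuple[float, float]] = field(default_factory=list)

    def volumes(self) -> list[float]:
        return [p[0] for p in self.points]

    def phs(self) -> list[float]:
        return [p[1] for p in self.points]

    def add(self, volume: float, ph: float) -> None:
        if self.points and volume <= self.points[-1][0]:
            raise ValueError("cumulative volume must strictly increase")
        self.points.append((volume, ph))


def _wait_for_stability(plant, reader, config: TitrationConfig,
                        tick: float = 1.0) -> float:
    """Step the plant until the pH settles; returns the settled pH."""
    window = max(1, int(round(config.stability_window / tick)))
    history = [reader()]
    waited = 0.0
    while True:
        if len(history) > window and \
                abs(history[-1] - history[-1 - window]) <= config.stability_epsilon:
            return history[-1]
        if waited >= config.stability_timeout:
            raise TitrationTimeout(
                f"pH did not stabilise within {config.stability_timeout} s")
        plant.step(tick)
        history.append(reader())
        waited += tick


def titrate(pump, plant, reader: Callable[[], float],
            config: TitrationConfig, tick: float = 1.0) -> TitrationCurve:
    """Run a stability-gated incremental titration.

    ``reader`` returns the current pH as the instrument reports it (e.g.
    OCR of the plant's display frame).  Each cycle waits for stability,
    records a point at the current cumulative delivered volume, then
    doses the next scheduled increment into the plant; the run stops at
    the end of the schedule or at ``max_volume``.  A never-settling pH
    raises :class:`TitrationTimeout` carrying the partial curve.
    """
    curve = TitrationCurve()
    delivered_total = 0.0

    def record():
        try:
            ph = _wait_for_stability(plant, reader, config, tick)
        except TitrationTimeout as e:
            e.partial_curve = curve
            raise
        # first point sits at volume 0; later points at the delivered total
        volume = delivered_total
        curve.points.append((volume, ph))

    record()
    for increment in config.increments():
        if delivered_total + increment > config.max_volume + 1e-12:
            break
        delivered = pump.dose(increment)
        pending = pump.take_pending() if hasattr(pump, "take_pending") else delivered
        plant.step(tick, added_ml=pending, molarity=pump.molarity)
        delivered_total += delivered
        record()
    return curve


@dataclass(frozen=True)
class EquivalenceResult:
    volume: float | None                 # ml of titrant; None if no equivalence
    method: str = "first_derivative"
    peak_slope: float = 0.0              # pH / ml at the detected peak

    @property
    def found(self) -> bool:
        return self.volume is not None


def equivalence_point(curve: TitrationCurve,
                      min_span: float = 1.0) -> EquivalenceResult:
    """First-derivative equivalence estimate with parabolic refinement.

    Central finite differences of pH against the (possibly uneven)
    cumulative-volume grid locate the steepest point; a parabola through
    the peak derivative and its neighbours refines the estimate off-grid.
    A curve spanning less than ``min_span`` pH units is reported as
    having no equivalence point (flat curve).
    """
    pts = curve.points
    if len(pts) < 5:
        raise ValueError("need at least 5 curve points")
    v = curve.volumes()
    p = curve.phs()
    for a, b in zip(v, v[1:]):
        if b <= a:
            raise ValueError("volumes must be strictly increasing")
    if max(p) - min(p) < min_span:
        return EquivalenceResult(None)

    # central differences on an uneven grid
    dv = [(p[i + 1] - p[i - 1]) / (v[i + 1] - v[i - 1])
          for i in range(1, len(pts) - 1)]
    centers = v[1:-1]
    k = max(range(len(dv)), key=lambda i: dv[i])
    refined = centers[k]
    if 0 < k < len(dv) - 1:
        x0, x1, x2 = centers[k - 1], centers[k], centers[k + 1]
        y0, y1, y2 = dv[k - 1], dv[k], dv[k + 1]
        # vertex of the parabola through three (volume, slope) points
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        if abs(denom) > 1e-15:
            a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
            b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0)
                 + x0 * x0 * (y1 - y2)) / denom
            if a < 0:
                refined = -b / (2.0 * a)
    return EquivalenceResult(refined, "first_derivative", dv[k])
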