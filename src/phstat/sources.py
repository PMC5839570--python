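"""Frame sources: anything with ``next_frame() -> (frame, timestamp)``.

Implementations: a file-glob source replaying recorded PNG frames, and a
renderer source synthesising frames from a value stream.  The simulated
plant provides its own source (:class:`phstat.plant.PlantFrameSource`);
a live camera source would implement the same contract.
"""

from __future__ import annotations

import glob as _glob
from pathlib import Path
from typing import Callable, Iterable, Iterator, Protocol

import numpy as np
from PIL import Image

from . import ocr

__all__ = ["FrameSource", "GlobFrameSource", "RenderedFrameSource",
           "read_frame", "write_frame"]


class FrameSource(Protocol):
    def next_frame(self) -> tuple[np.ndarray, float]: ...


def read_frame(path) -> np.ndarray:
    """Load a PNG (or any pillow-readable image) as an RGB frame array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def write_frame(path, frame: np.ndarray) -> None:
    Image.fromarray(np.asarray(frame, dtype=np.uint8), mode="RGB").save(path)


class GlobFrameSource:
    """Replays image files matching a glob pattern, in sorted order.

    Timestamps are synthesised at ``1/fps`` spacing.  Raises
    StopIteration when the files run out.
    """

    def __init__(self, pattern: str, fps: float = 10.0):
        self.paths = sorted(_glob.glob(str(pattern)))
        self.fps = fps
        self._i = 0

    def __len__(self) -> int:
        return len(self.paths)

    def next_frame(self) -> tuple[np.ndarray, float]:
        if self._i >= len(self.paths):
            raise StopIteration("frame files exhausted")
        frame = read_frame(self.paths[self._i])
        t = self._i / self.fps
        self._i += 1
        return frame, t


class RenderedFrameSource:
    """Synthesises frames from a pH value stream through the renderer."""

    def __init__(self, values: Iterable[float] | Callable[[float], float],
                 geometry: ocr.SegmentGeometry,
                 style: ocr.RenderStyle = ocr.RenderStyle(),
                 rng: np.random.Generator | None = None,
                 dt: float = 1.0):
        self._values: Iterator[float] | None
        self._fn: Callable[[float], float] | None
        if callable(values):
            self._values, self._fn = None, values
        else:
            self._values, self._fn = iter(values), None
        self.geometry = geometry
        self.style = style
        self.rng = rng
        self.dt = dt
        self._t = 0.0

    def next_frame(self) -> tuple[np.ndarray, float]:
        t = self._t
        self._t += self.dt
        value = self._fn(t) if self._fn is not None else next(self._values)
        frame = ocr.render_display(value, self.geometry, self.style, self.rng)
        return frame, t
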