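"""Seven-segment display OCR with a synthetic display renderer.

Many bench pH meters expose their measurement only on a red seven-segment
LED display.  This module decodes such a display from an RGB camera frame:
the red channel is thresholded, seven thin probe regions per digit are
sampled, and the resulting on/off pattern is looked up in the canonical
seven-segment digit map.  A renderer producing red-dominant frames of any
representable value (with optional Gaussian pixel noise and deliberately
corrupted "transition" digits) closes the loop so the decoder can be
exercised without a camera.

Conventions
-----------
* Frames are ``(height, width, 3)`` uint8 arrays, channel order RGB,
  pixel coordinates 0-based, row-major, origin top-left.
* Segments carry their canonical labels: a=top, b=top-right,
  c=bottom-right, d=bottom, e=bottom-left, f=top-left, g=middle.
* The display has a fixed decimal point: ``decimal_index`` counts the
  integer digits, so a 5-digit display with ``decimal_index=2`` shows
  values 0.000–99.999 with millesimal resolution.
* Binarisation is strict: a pixel is "on" iff intensity > threshold.
* Leading blank digits are zero-valued placeholders (displays blank
  leading zeros); a blank after a lit digit invalidates the reading, as
  do minus signs and unrecognised patterns — mid-transition frames must
  be rejected, never misread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .exceptions import CalibrationError, GeometryError

__all__ = [
    "BLANK",
    "MINUS",
    "INVALID",
    "SEGMENTS",
    "GLYPH_SEGMENTS",
    "SegmentGeometry",
    "OcrCalibration",
    "RenderStyle",
    "Reading",
    "red_channel",
    "binarize",
    "probe_boxes",
    "sample_pattern",
    "decode_digit",
    "decode_display",
    "glyphs_for_value",
    "render_display",
    "render_patterns",
    "auto_threshold",
]

SEGMENTS = "abcdefg"

#: sentinels returned by :func:`decode_digit` besides the digits 0–9
BLANK = "blank"
MINUS = "minus"
INVALID = "invalid"

Glyph = Union[int, str]

#: canonical seven-segment encoding of each displayable glyph
GLYPH_SEGMENTS: Mapping[Glyph, frozenset] = {
    0: frozenset("abcdef"),
    1: frozenset("bc"),
    2: frozenset("abdeg"),
    3: frozenset("abcdg"),
    4: frozenset("bcfg"),
    5: frozenset("acdfg"),
    6: frozenset("acdefg"),
    7: frozenset("abc"),
    8: frozenset("abcdefg"),
    9: frozenset("abcdfg"),
    BLANK: frozenset(),
    MINUS: frozenset("g"),
}

_PATTERN_TO_GLYPH = {v: k for k, v in GLYPH_SEGMENTS.items()}


# --------------------------------------------------------------------------
# geometry and calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentGeometry:
    """Where the digits live on a frame.

    ``anchor_row``/``anchor_col`` locate the top-left corner of the first
    digit's bounding box; successive digits repeat every ``digit_pitch``
    columns.  ``decimal_index`` is the number of integer digits, i.e. the
    fixed decimal point sits after that many digits.
    """

    anchor_row: int
    anchor_col: int
    digit_width: int
    digit_height: int
    digit_pitch: int
    n_digits: int = 5
    decimal_index: int = 2

    def __post_init__(self):
        if self.digit_width < 3 or self.digit_height < 5:
            raise GeometryError("digit box must be at least 3x5 pixels")
        if self.digit_pitch < self.digit_width:
            raise GeometryError("digit_pitch must be >= digit_width")
        if not (0 <= self.decimal_index < self.n_digits):
            raise GeometryError("decimal_index must lie in [0, n_digits)")
        if self.n_digits < 1:
            raise GeometryError("need at least one digit")
        if self.anchor_row < 0 or self.anchor_col < 0:
            raise GeometryError("anchors must be non-negative")

    @property
    def fractional_digits(self) -> int:
        return self.n_digits - self.decimal_index

    @property
    def resolution(self) -> float:
        """Smallest representable increment (one least-significant digit)."""
        return 10.0 ** -self.fractional_digits

    def digit_box(self, index: int) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) of digit ``index`` (half-open)."""
        if not (0 <= index < self.n_digits):
            raise GeometryError(f"digit index {index} out of range")
        c0 = self.anchor_col + index * self.digit_pitch
        return (self.anchor_row, self.anchor_row + self.digit_height,
                c0, c0 + self.digit_width)

    def check_fits(self, height: int, width: int) -> None:
        r0, r1, _, _ = self.digit_box(0)
        _, _, c0, c1 = self.digit_box(self.n_digits - 1)
        if r0 < 0 or r1 > height or c1 > width:
            raise GeometryError(
                f"digit boxes (rows {r0}:{r1}, cols ..{c1}) exceed "
                f"frame {height}x{width}")

    def frame_shape(self) -> tuple[int, int]:
        """Smallest symmetric frame around the digits (used by the renderer)."""
        h = 2 * self.anchor_row + self.digit_height
        w = (2 * self.anchor_col + (self.n_digits - 1) * self.digit_pitch
             + self.digit_width)
        return h, w


@dataclass(frozen=True)
class OcrCalibration:
    """Threshold + geometry + probe vote fraction: everything decoding needs."""

    threshold: int
    geometry: SegmentGeometry
    on_fraction: float = 0.5

    def __post_init__(self):
        if not (0 <= self.threshold <= 255):
            raise ValueError("threshold must be in [0, 255]")
        if not (0.0 < self.on_fraction <= 1.0):
            raise ValueError("on_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Reading:
    """A timestamped decoded display value.

    ``value`` is NaN when ``valid`` is False; valid values always lie in
    the display-representable range.
    """

    value: float
    valid: bool
    timestamp: float = 0.0


# --------------------------------------------------------------------------
# decoding pipeline
# --------------------------------------------------------------------------

def _as_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB frame, got {frame.shape}")
    return frame


def red_channel(frame: np.ndarray) -> np.ndarray:
    """Extract the red plane — the signal carrier on red LED displays."""
    return _as_frame(frame)[:, :, 0]


def binarize(gray: np.ndarray, threshold: int) -> np.ndarray:
    """Boolean grid: pixel on iff intensity strictly above ``threshold``."""
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    return np.asarray(gray) > threshold


def probe_thickness(geometry: SegmentGeometry) -> int:
    return max(1, geometry.digit_height // 10)


def probe_boxes(geometry: SegmentGeometry) -> dict[str, tuple[int, int, int, int]]:
    """Probe rectangles per segment, relative to the digit box (half-open).

    Each segment is sampled in a thin rectangle at its standard relative
    position: a/g/d across the horizontal centre band at top/middle/bottom,
    b/c on the right edge at quarter heights, f/e mirrored on the left.
    """
    w, h = geometry.digit_width, geometry.digit_height
    th = probe_thickness(geometry)
    cm = max(1, w // 4)            # horizontal inset keeps clear of b/c/e/f bars
    vh = max(1, h // 4)            # vertical probe extent
    g0 = h // 2 - th // 2
    up, lo = h // 4, (3 * h) // 4  # vertical probe centres
    u0 = up - vh // 2
    l0 = lo - vh // 2
    return {
        "a": (0, th, cm, w - cm),
        "g": (g0, g0 + th, cm, w - cm),
        "d": (h - th, h, cm, w - cm),
        "f": (u0, u0 + vh, 0, th),
        "b": (u0, u0 + vh, w - th, w),
        "e": (l0, l0 + vh, 0, th),
        "c": (l0, l0 + vh, w - th, w),
    }


def sample_pattern(binary: np.ndarray, geometry: SegmentGeometry,
                   digit_index: int, on_fraction: float = 0.5) -> frozenset:
    """Lit-segment set of one digit: probe region vote at ``on_fraction``."""
    binary = np.asarray(binary)
    geometry.check_fits(*binary.shape[:2])
    r0, _, c0, _ = geometry.digit_box(digit_index)
    lit = set()
    for seg, (pr0, pr1, pc0, pc1) in probe_boxes(geometry).items():
        region = binary[r0 + pr0:r0 + pr1, c0 + pc0:c0 + pc1]
        if region.size and region.mean() >= on_fraction:
            lit.add(seg)
    return frozenset(lit)


def decode_digit(pattern) -> Glyph:
    """Exact lookup in the canonical map; unknown patterns are INVALID."""
    return _PATTERN_TO_GLYPH.get(frozenset(pattern), INVALID)


def decode_display(frame: np.ndarray, cal: OcrCalibration,
                   timestamp: float = 0.0) -> Reading:
    """Decode a full display frame into a :class:`Reading`.

    Leading blanks read as zeros (blanked leading zeros); any INVALID
    pattern, any minus sign, or a blank after a lit digit marks the
    reading invalid — a conservative rule that rejects mid-transition
    frames rather than risking a wrong number.
    """
    frame = _as_frame(frame)
    geo = cal.geometry
    geo.check_fits(frame.shape[0], frame.shape[1])
    binary = binarize(red_channel(frame), cal.threshold)
    glyphs = [sample_pattern(binary, geo, i, cal.on_fraction)
              for i in range(geo.n_digits)]
    glyphs = [decode_digit(p) for p in glyphs]

    seen_digit = False
    digits = []
    for g in glyphs:
        if g == INVALID or g == MINUS:
            return Reading(float("nan"), False, timestamp)
        if g == BLANK:
            if seen_digit:
                return Reading(float("nan"), False, timestamp)
            digits.append(0)
        else:
            seen_digit = True
            digits.append(g)
    if not seen_digit:
        return Reading(float("nan"), False, timestamp)

    scaled = 0
    for d in digits:
        scaled = scaled * 10 + d
    value = scaled / 10 ** geo.fractional_digits
    return Reading(value, True, timestamp)


# --------------------------------------------------------------------------
# synthetic renderer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderStyle:
    """Appearance of rendered frames.

    Red carries the signal (lit segments at ``on_intensity``, unlit bars
    ghosting at ``off_intensity``, everything else at ``background``);
    green and blue stay at background level.  ``noise_sd`` adds clipped
    Gaussian pixel noise to every channel.  ``segment_thickness`` defaults
    to a size that fully covers the decoder's probe rectangles.
    """

    on_intensity: int = 230
    off_intensity: int = 30
    background: int = 10
    noise_sd: float = 0.0
    segment_thickness: int | None = None
    decimal_point: bool = True


def _bar_thickness(geometry: SegmentGeometry, style: RenderStyle) -> int:
    if style.segment_thickness is not None:
        return style.segment_thickness
    w, h = geometry.digit_width, geometry.digit_height
    return max(1, min(h // 8, w // 4), probe_thickness(geometry))


def _segment_bars(w: int, h: int, t: int) -> dict[str, tuple[int, int, int, int]]:
    """Full segment bars (classic block digit with corner insets)."""
    ch = h // 2
    g0 = ch - t // 2
    return {
        "a": (0, t, t, w - t),
        "g": (g0, g0 + t, t, w - t),
        "d": (h - t, h, t, w - t),
        "f": (t, ch, 0, t),
        "b": (t, ch, w - t, w),
        "e": (ch, h - t, 0, t),
        "c": (ch, h - t, w - t, w),
    }


def glyphs_for_value(value: float, geometry: SegmentGeometry) -> list[Glyph]:
    """Digit glyphs a display would show for ``value`` (leading zeros blanked)."""
    n, frac = geometry.n_digits, geometry.fractional_digits
    scaled = int(round(value * 10 ** frac))
    if scaled < 0 or scaled >= 10 ** n:
        raise ValueError(
            f"value {value} not representable on {n} digits with "
            f"{frac} decimals")
    text = str(scaled).rjust(n, "0")
    glyphs: list[Glyph] = [int(c) for c in text]
    # blank leading zeros of the integer part, keeping its last digit
    for i in range(geometry.decimal_index - 1):
        if glyphs[i] == 0:
            glyphs[i] = BLANK
        else:
            break
    return glyphs


def render_patterns(patterns: Sequence[frozenset], geometry: SegmentGeometry,
                    style: RenderStyle = RenderStyle(),
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Render explicit per-digit segment patterns (corruption injection)."""
    if len(patterns) != geometry.n_digits:
        raise GeometryError("one pattern per digit required")
    h, w = geometry.frame_shape()
    frame = np.full((h, w, 3), style.background, dtype=float)
    t = _bar_thickness(geometry, style)
    bars = _segment_bars(geometry.digit_width, geometry.digit_height, t)
    for i, pattern in enumerate(patterns):
        r0, _, c0, _ = geometry.digit_box(i)
        for seg, (br0, br1, bc0, bc1) in bars.items():
            level = style.on_intensity if seg in pattern else style.off_intensity
            frame[r0 + br0:r0 + br1, c0 + bc0:c0 + bc1, 0] = level
    if style.decimal_point and 0 < geometry.decimal_index < geometry.n_digits:
        gap = geometry.digit_pitch - geometry.digit_width
        if gap >= 2:
            _, r1, _, c1 = geometry.digit_box(geometry.decimal_index - 1)
            dc = c1 + gap // 2 - t // 2
            frame[r1 - t:r1, dc:dc + t, 0] = style.on_intensity
    if style.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        frame += rng.normal(0.0, style.noise_sd, frame.shape)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def render_display(value: float, geometry: SegmentGeometry,
                   style: RenderStyle = RenderStyle(),
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Render the frame a red seven-segment display would show for ``value``."""
    patterns = [GLYPH_SEGMENTS[g] for g in glyphs_for_value(value, geometry)]
    return render_patterns(patterns, geometry, style, rng)


# --------------------------------------------------------------------------
# threshold calibration
# --------------------------------------------------------------------------

def auto_threshold(frame: np.ndarray, geometry: SegmentGeometry,
                   known_value: float, on_fraction: float = 0.5) -> int:
    """Pick a binarisation threshold from a frame showing a known value.

    Scans all 256 thresholds, finds every one for which the frame decodes
    to ``known_value``, and returns the midpoint of the widest contiguous
    working interval — the choice most robust to lighting drift.
    """
    geometry.check_fits(frame.shape[0], frame.shape[1])
    frac = geometry.fractional_digits
    target = int(round(known_value * 10 ** frac))
    ok = np.zeros(256, dtype=bool)
    for t in range(256):
        r = decode_display(frame, OcrCalibration(t, geometry, on_fraction))
        ok[t] = r.valid and int(round(r.value * 10 ** frac)) == target
    if not ok.any():
        raise CalibrationError(
            f"no threshold in [0, 255] decodes the frame to {known_value}")
    best_start = best_len = 0
    start = None
    for t in range(257):
        if t < 256 and ok[t]:
            if start is None:
                start = t
        elif start is not None:
            if t - start > best_len:
                best_start, best_len = start, t - start
            start = None
    return best_start + (best_len - 1) // 2
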