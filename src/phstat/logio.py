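"""CSV log and calibration-table I/O.

Logs are plain ASCII CSV with the header ``time_s,pH,cumulative_volume_ml``
— one row per second of run, readable by any stats package.  Numbers are
written with fixed precision (pH and volume to 3 decimals) so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

from .controller import LogRecord
from .exceptions import LogParseError
from .pumps import CalibrationMeasurement
from .titration import TitrationCurve

__all__ = [
    "LOG_HEADER",
    "write_log",
    "read_log",
    "write_curve",
    "read_curve",
    "read_calibration_table",
    "write_calibration_table",
]

LOG_HEADER = ["time_s", "pH", "cumulative_volume_ml"]
CURVE_HEADER = ["cumulative_volume_ml", "pH"]
CAL_HEADER = ["run_time", "measured_volume"]


def write_log(path, records: Sequence[LogRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LOG_HEADER)
        for r in records:
            w.writerow([f"{r.t:.1f}", f"{r.ph:.3f}",
                        f"{r.cumulative_volume:.3f}"])


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise LogParseError(f"non-numeric {what}: {text!r}", lineno) from None


def read_log(path) -> list[LogRecord]:
    """Read a log CSV; malformed rows raise LogParseError with the line."""
    records: list[LogRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        return records
    if [c.strip() for c in rows[0]] != LOG_HEADER:
        raise LogParseError(f"unexpected header {rows[0]!r}", 1)
    prev_t = -math.inf
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 3:
            raise LogParseError(f"expected 3 columns, got {len(row)}", lineno)
        t = _parse_float(row[0], "time", lineno)
        ph = _parse_float(row[1], "pH", lineno)
        vol = _parse_float(row[2], "volume", lineno)
        if t <= prev_t:
            raise LogParseError("time must strictly increase", lineno)
        prev_t = t
        records.append(LogRecord(t, ph, vol))
    return records


def write_curve(path, curve: TitrationCurve) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CURVE_HEADER)
        for vol, ph in curve.points:
            w.writerow([f"{vol:.3f}", f"{ph:.3f}"])


def read_curve(path) -> TitrationCurve:
    curve = TitrationCurve()
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        return curve
    if [c.strip() for c in rows[0]] != CURVE_HEADER:
        raise LogParseError(f"unexpected header {rows[0]!r}", 1)
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        vol = _parse_float(row[0], "volume", lineno)
        ph = _parse_float(row[1], "pH", lineno)
        curve.add(vol, ph)
    return curve


def read_calibration_table(path) -> list[CalibrationMeasurement]:
    """Pump calibration measurements: columns run_time, measured_volume."""
    out: list[CalibrationMeasurement] = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        return out
    if [c.strip() for c in rows[0]] != CAL_HEADER:
        raise LogParseError(f"unexpected header {rows[0]!r}", 1)
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        rt = _parse_float(row[0], "run_time", lineno)
        mv = _parse_float(row[1], "measured_volume", lineno)
        out.append(CalibrationMeasurement(rt, mv))
    return out


def write_calibration_table(path, measurements: Iterable[CalibrationMeasurement]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CAL_HEADER)
        for m in measurements:
            w.writerow([f"{m.run_time:g}", f"{m.measured_volume:g}"])
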