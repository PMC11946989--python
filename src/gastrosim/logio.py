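"""Plain-text pressure logs and run manifests.

A log file holds one header line and three columns: elapsed time (s),
relative pressure (mmHg), and motor speed (signed PWM; the external
disturbance pump for spike protocols, the control command otherwise).
Values are serialized at four decimals, matching the acquisition chain's
reporting precision, so a write/read round trip is exact at that
quantization.  The reader accepts whitespace-, tab- and comma-delimited
dialects.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

HEADER = ("elapsed_time_s", "relative_pressure_mmhg", "motor_speed_pwm")
_SPLIT = re.compile(r"[,\t ]+")


@dataclass(frozen=True)
class LogRecord:
    """One logged sample of the three-column record."""

    elapsed_time: float
    relative_pressure: float
    motor_speed: float


class LogParseError(ValueError):
    """Malformed log content; the message names the offending line."""


def write_log(records, path) -> None:
    """Write time-ordered records as whitespace-delimited text."""
    times = [r.elapsed_time for r in records]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("records must be strictly time-ordered")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(" ".join(HEADER) + "\n")
        for r in records:
            fh.write(f"{r.elapsed_time:.4f} {r.relative_pressure:.4f} "
                     f"{r.motor_speed:.4f}\n")


def read_log(path) -> list[LogRecord]:
    """Parse a three-column log file (whitespace, tab or CSV dialect)."""
    path = Path(path)
    records: list[LogRecord] = []
    with path.open() as fh:
        lines = fh.readlines()
    if not lines:
        raise LogParseError(f"{path}: empty file, expected a header line")
    header = _SPLIT.split(lines[0].strip())
    if len(header) != 3:
        raise LogParseError(
            f"{path}: line 1: expected 3 columns in header, got {len(header)}")
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line:
            continue
        fields = _SPLIT.split(line)
        if len(fields) != 3:
            raise LogParseError(
                f"{path}: line {lineno}: expected 3 columns, got {len(fields)}")
        try:
            t, p, m = (float(f) for f in fields)
        except ValueError as exc:
            raise LogParseError(
                f"{path}: line {lineno}: non-numeric field: {exc}") from None
        records.append(LogRecord(t, p, m))
    return records


def log_to_arrays(records):
    """Column arrays (time, pressure, motor) from a record list."""
    import numpy as np
    return (np.array([r.elapsed_time for r in records]),
            np.array([r.relative_pressure for r in records]),
            np.array([r.motor_speed for r in records]))


@dataclass
class RunManifest:
    """Reproducibility sidecar for an emitted log: the configuration
    snapshot, seed and timestamps sufficient to regenerate it."""

    config: dict
    seed: int
    started_utc: str = ""
    finished_utc: str = ""
    version: str = "0.1.0"

    @staticmethod
    def now() -> str:
        return datetime.now(timezone.utc).isoformat()

    def write(self, log_path) -> Path:
        out = Path(str(log_path) + ".manifest.json")
        out.write_text(json.dumps(asdict(self), indent=2, default=str))
        return out
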