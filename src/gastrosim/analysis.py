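"""Statistics for pressure logs.

Implements the analysis pipeline applied to the control experiments:

* Bland-Altman agreement (mean bias, SD, SE, 1.96-SD limits of agreement;
  the limits are the interval expected to contain ~95% of paired
  differences between two measurement methods);
* step-response settling time (5-sample moving average entering a
  setpoint band);
* spike segmentation by external-motor-speed threshold crossings with
  first-spike exclusion, and per-spike recovery time (reach and remain
  within a tolerance of the setpoint);
* steady-state summaries (mean, SD, SE, 95% CI, steady-state error);
* intra-abdominal hypertension (IAH) grading per the WSACS thresholds.

All sample standard deviations use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import constants as C
from .logio import LogRecord


@dataclass(frozen=True)
class BlandAltmanResult:
    """One row of a Bland-Altman agreement table (all mmHg except n)."""

    mean_diff: float
    sd: float
    se: float
    loa_lower: float
    loa_upper: float
    n: int


@dataclass(frozen=True)
class SpikeSegment:
    """One disturbance burst plus its monitoring window."""

    start: float
    end: float
    peak_deviation: float
    response_time: float | None  # None = not applicable (never recovered)


@dataclass(frozen=True)
class SteadySummary:
    mean: float
    sd: float
    se: float
    ci95: tuple[float, float]
    steady_state_error: float


class IahGrade(Enum):
    """WSACS intra-abdominal hypertension grades."""

    NONE = "none"
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


def _pressures(trace) -> np.ndarray:
    if len(trace) and isinstance(trace[0], LogRecord):
        return np.array([r.relative_pressure for r in trace], dtype=float)
    return np.asarray(trace, dtype=float)


def _times(trace) -> np.ndarray:
    return np.array([r.elapsed_time for r in trace], dtype=float)


def bland_altman(differences) -> BlandAltmanResult:
    """Agreement statistics of paired differences.

    mean_diff is the bias, sd the sample SD, se = sd/sqrt(n), and the
    limits of agreement are mean_diff +/- 1.96*sd.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 differences")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    se = float(sd / np.sqrt(d.size))
    return BlandAltmanResult(mean_diff=mean, sd=sd, se=se,
                             loa_lower=mean - 1.96 * sd,
                             loa_upper=mean + 1.96 * sd, n=int(d.size))


def bland_altman_from_stats(mean_diff: float, sd: float,
                            n: int) -> BlandAltmanResult:
    """Agreement table row from already-computed bias and SD.

    Useful for checking printed summary rows: se = sd/sqrt(n) and the
    limits of agreement follow from the same 1.96-SD formula as
    :func:`bland_altman`.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return BlandAltmanResult(mean_diff=mean_diff, sd=sd,
                             se=sd / np.sqrt(n),
                             loa_lower=mean_diff - 1.96 * sd,
                             loa_upper=mean_diff + 1.96 * sd, n=int(n))


def response_time_step(trace, target: float,
                       band: float = C.STEP_RESPONSE_BAND_MMHG,
                       window: int = C.STEP_RESPONSE_WINDOW) -> float | None:
    """Settling time by the moving-average criterion.

    Returns the elapsed time (from the first sample of ``trace``, i.e.
    control activation) of the last sample of the first ``window``-long
    run whose mean pressure lies within ``target +/- band``; ``None`` if
    the criterion is never met.
    """
    if len(trace) < window:
        raise ValueError(f"trace shorter than the {window}-sample window")
    p = _pressures(trace)
    t = _times(trace) if isinstance(trace[0], LogRecord) else \
        np.arange(len(trace), dtype=float)
    kernel = np.ones(window) / window
    means = np.convolve(p, kernel, mode="valid")
    hits = np.flatnonzero(np.abs(means - target) <= band)
    if hits.size == 0:
        return None
    last_idx = hits[0] + window - 1
    return float(t[last_idx] - t[0])


def segment_spikes(log, speed_threshold: float = C.SPIKE_SPEED_THRESHOLD_PWM,
                   target: float = C.SETPOINT_MMHG,
                   tol: float = C.SPIKE_RECOVERY_TOL_MMHG,
                   debounce: float = 1.0) -> list[SpikeSegment]:
    """Split a spike-protocol log into per-burst segments.

    A segment opens where the external motor speed magnitude crosses
    above ``speed_threshold`` and closes at the next such crossing (or
    the log end).  Crossings within ``debounce`` seconds of the previous
    one are merged.  The first detected segment is discarded to avoid
    start-up instability.  Each returned segment carries the peak
    pressure deviation from ``target`` and the recovery time per
    :func:`response_time_spike`.
    """
    if not len(log):
        raise ValueError("empty log")
    t = _times(log)
    p = _pressures(log)
    speed = np.abs(np.array([r.motor_speed for r in log], dtype=float))
    above = speed > speed_threshold
    rising = np.flatnonzero(above & ~np.concatenate(([True], above[:-1])))
    if above[0]:
        rising = np.concatenate(([0], rising))
    # debounce: drop crossings within `debounce` seconds of the kept one
    kept: list[int] = []
    for idx in rising:
        if not kept or t[idx] - t[kept[-1]] > debounce:
            kept.append(int(idx))
    segments: list[SpikeSegment] = []
    for j, start_idx in enumerate(kept):
        end_idx = kept[j + 1] if j + 1 < len(kept) else len(log)
        seg_t = t[start_idx:end_idx]
        seg_p = p[start_idx:end_idx]
        seg = [log[i] for i in range(start_idx, end_idx)]
        segments.append(SpikeSegment(
            start=float(seg_t[0]), end=float(seg_t[-1]),
            peak_deviation=float(np.max(np.abs(seg_p - target))),
            response_time=response_time_spike(seg, target, tol)))
    return segments[1:]


def response_time_spike(segment, target: float,
                        tol: float = C.SPIKE_RECOVERY_TOL_MMHG) -> float | None:
    """Recovery time within a spike segment.

    Time from the segment start until the earliest sample after which
    every remaining sample lies within ``target +/- tol``; ``None`` when
    the segment ends outside the band (not applicable).
    """
    if not len(segment):
        raise ValueError("empty segment")
    p = _pressures(segment)
    t = _times(segment) if isinstance(segment[0], LogRecord) else \
        np.arange(len(segment), dtype=float)
    inside = np.abs(p - target) <= tol
    # suffix scan: earliest index from which all remaining samples are inside
    if not inside[-1]:
        return None
    idx = len(inside) - 1
    while idx > 0 and inside[idx - 1]:
        idx -= 1
    return float(t[idx] - t[0])


def summarize_steady_state(trace, setpoint: float) -> SteadySummary:
    """Mean/SD/SE, 95% CI of the mean, and steady-state error."""
    p = _pressures(trace)
    if p.size < 2:
        raise ValueError("steady-state summary needs at least 2 samples")
    mean = float(np.mean(p))
    sd = float(np.std(p, ddof=1))
    se = float(sd / np.sqrt(p.size))
    return SteadySummary(mean=mean, sd=sd, se=se,
                         ci95=(mean - 1.96 * se, mean + 1.96 * se),
                         steady_state_error=abs(mean - setpoint))


def classify_iah(pressure: float) -> IahGrade:
    """WSACS grade of an intra-abdominal pressure reading (mmHg):
    below 12 none, 12-16 I, 16-21 II, 21-25 III, above 25 IV."""
    t1, t2, t3, t4 = C.IAH_THRESHOLDS_MMHG
    if pressure < t1:
        return IahGrade.NONE
    if pressure < t2:
        return IahGrade.I
    if pressure < t3:
        return IahGrade.II
    if pressure <= t4:
        return IahGrade.III
    return IahGrade.IV
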