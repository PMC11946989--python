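"""Simulated physiological disturbances applied to the plant.

Two mechanisms mirror the experimental rig:

* **cough / belch** — timed bursts of an external pump at maximum speed
  (positive PWM pushes air in, negative pulls it out), injected as flow;
* **breathing** — a sinusoidal additive pressure offset (amplitude in
  mmHg, frequency in cycles/min) superimposed on the cavity pressure.

A :class:`DisturbanceSchedule` combines an ordered list of burst events
with an optional breathing waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C


@dataclass(frozen=True)
class SpikeParams:
    """Burst protocol parameters: N bursts of ``spike_duration`` s at
    ``magnitude`` PWM, each followed by a ``gap``-long monitoring window."""

    kind: str = "cough"  # "cough" (positive) or "belch" (negative)
    count: int = C.SPIKE_COUNT
    spike_duration: float = C.SPIKE_DURATION_S
    gap: float = C.SPIKE_GAP_S
    magnitude: float = float(C.SPIKE_MAGNITUDE_PWM)

    def __post_init__(self) -> None:
        if self.kind not in ("cough", "belch"):
            raise ValueError("kind must be 'cough' or 'belch'")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.spike_duration <= 0:
            raise ValueError("spike_duration must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if not 0 < self.magnitude <= C.PWM_MAX:
            raise ValueError("magnitude must lie in (0, 255]")


@dataclass(frozen=True)
class BreathingParams:
    """Sinusoidal respiratory pressure oscillation."""

    amplitude: float = C.BREATHING_AMPLITUDE_MMHG
    frequency: float = C.BREATHING_FREQUENCY_CPM  # cycles per minute
    duration: float = C.BREATHING_DURATION_S

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class DisturbanceSchedule:
    """Time-ordered, non-overlapping external-pump events plus an
    optional breathing waveform."""

    events: tuple[tuple[float, float, float], ...] = ()  # (start, end, pwm)
    breathing: BreathingParams | None = None

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end, _pwm in self.events:
            if not start < end:
                raise ValueError("event must have start < end")
            if start < prev_end:
                raise ValueError("events overlap or are unordered")
            prev_end = end

    def external_pwm(self, t: float) -> float:
        """External-pump PWM active at time ``t`` (0 outside events)."""
        for start, end, pwm in self.events:
            if start <= t < end:
                return pwm
            if t < start:
                break
        return 0.0

    def pressure_offset(self, t: float) -> float:
        """Additive breathing pressure offset at time ``t`` (mmHg)."""
        if self.breathing is None or t > self.breathing.duration:
            return 0.0
        return breathing_offset(t, self.breathing)


def spike_schedule(params: SpikeParams, start: float = 0.0) -> DisturbanceSchedule:
    """Regular burst train: burst k begins at ``start + k*(duration+gap)``.

    Cough bursts carry +magnitude PWM, belch bursts -magnitude.
    """
    sign = 1.0 if params.kind == "cough" else -1.0
    events = tuple(
        (start + k * (params.spike_duration + params.gap),
         start + k * (params.spike_duration + params.gap) + params.spike_duration,
         sign * params.magnitude)
        for k in range(params.count)
    )
    return DisturbanceSchedule(events=events)


def breathing_offset(t: float, params: BreathingParams) -> float:
    """``amplitude * sin(2*pi*(frequency/60)*t)`` mmHg."""
    return params.amplitude * math.sin(2.0 * math.pi * params.frequency / 60.0 * t)


def mixed_schedule(duration: float, n_cough: int, n_belch: int,
                   params: SpikeParams, rng: np.random.Generator,
                   breathing: BreathingParams | None = None
                   ) -> DisturbanceSchedule:
    """Randomly placed cough and belch bursts over ``[0, duration]`` with
    continuous breathing.

    Start times are drawn uniformly and accepted only if every pair of
    bursts is separated by at least ``spike_duration`` (rejection
    sampling), so events never overlap.
    """
    n_total = n_cough + n_belch
    if n_total * params.spike_duration > duration:
        raise ValueError("events do not fit in the requested duration")
    if breathing is None:
        breathing = BreathingParams(duration=duration)

    starts: list[float] = []
    max_start = duration - params.spike_duration
    attempts = 0
    while len(starts) < n_total:
        candidate = float(rng.uniform(0.0, max_start))
        if all(abs(candidate - s) >= params.spike_duration for s in starts):
            starts.append(candidate)
        attempts += 1
        if attempts > 100_000:
            raise ValueError("could not place events without overlap")

    signs = [1.0] * n_cough + [-1.0] * n_belch
    rng.shuffle(signs)
    events = tuple(sorted(
        (s, s + params.spike_duration, sign * params.magnitude)
        for s, sign in zip(starts, signs)
    ))
    return DisturbanceSchedule(events=events, breathing=breathing)
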