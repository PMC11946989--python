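"""Adaptive dual-gain PID controller with setpoint stop and pump arbitration.

The controller regulates gauge pressure to a 10.0 mmHg setpoint.  It
schedules between two gain sets on error magnitude: an *aggressive* set
(P 40, I 10.05, D 20.0) for large deviations and a *conservative* set
(P 4, I 10.2, D 40) near the target.  When the magnitude of the error
falls inside a small stop band the pumps are switched off entirely and
the integrator is frozen, mirroring the hardware's automatic pump stop at
the setpoint.  A single signed command drives either the air pump
(positive) or the suction pump (negative), never both.

Anti-windup is conditional integration: the integral is clamped so its
contribution never exceeds the output limit, and accumulation is skipped
while the output is saturated in the direction the error would deepen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import constants as C


@dataclass(frozen=True)
class GainSet:
    """PID gains mapping mmHg-domain terms to PWM counts."""

    kp: float  # PWM per mmHg
    ki: float  # PWM per (mmHg*s)
    kd: float  # PWM per (mmHg/s)

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("PID gains must be non-negative")


AGGRESSIVE = GainSet(C.AGGRESSIVE_KP, C.AGGRESSIVE_KI, C.AGGRESSIVE_KD)
CONSERVATIVE = GainSet(C.CONSERVATIVE_KP, C.CONSERVATIVE_KI, C.CONSERVATIVE_KD)


@dataclass(frozen=True)
class ControllerConfig:
    setpoint: float = C.SETPOINT_MMHG
    aggressive: GainSet = AGGRESSIVE
    conservative: GainSet = CONSERVATIVE
    switch_threshold: float = C.SWITCH_THRESHOLD_MMHG
    stop_band: float = C.STOP_BAND_MMHG
    output_limit: float = float(C.PWM_MAX)
    integral_limit: float = float(C.PWM_MAX)
    derivative_on_measurement: bool = False
    #: Clear the integrator when the stop band is entered (the pump-stop
    #: acts as a fresh start); False keeps it frozen instead.
    integral_reset_on_stop: bool = True

    def __post_init__(self) -> None:
        if not self.switch_threshold > self.stop_band >= 0:
            raise ValueError("require switch_threshold > stop_band >= 0")
        if self.output_limit <= 0:
            raise ValueError("output_limit must be positive")


@dataclass(frozen=True)
class ControllerState:
    """Integrator and derivative memory of the loop."""

    integral: float = 0.0       # mmHg*s
    previous_error: float = 0.0
    previous_measured: float = 0.0
    initialized: bool = False


@dataclass(frozen=True)
class PumpCommand:
    """Duty commands for the two pumps; at most one is nonzero."""

    air_pwm: float = 0.0
    suction_pwm: float = 0.0


def select_gains(error: float, config: ControllerConfig) -> GainSet:
    """Aggressive gains for |error| above the switch threshold, else
    conservative; a tie at the boundary resolves to conservative."""
    return config.aggressive if abs(error) > config.switch_threshold \
        else config.conservative


def pid_step(state: ControllerState, measured: float, dt: float,
             config: ControllerConfig) -> tuple[float, ControllerState]:
    """One discrete PID update; returns (signed PWM command, new state).

    The derivative acts on the error (or, behind the config flag, on the
    measurement) and is initialized on the first call so a setpoint step
    produces no derivative kick.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    error = config.setpoint - measured
    if not state.initialized:
        state = replace(state, previous_error=error,
                        previous_measured=measured, initialized=True)

    if abs(error) <= config.stop_band:
        # inside the stop band: pumps off, integrator cleared (or frozen)
        integral = 0.0 if config.integral_reset_on_stop else state.integral
        new_state = replace(state, integral=integral, previous_error=error,
                            previous_measured=measured)
        return 0.0, new_state

    gains = select_gains(error, config)
    if config.derivative_on_measurement:
        derivative = -(measured - state.previous_measured) / dt
    else:
        derivative = (error - state.previous_error) / dt

    integral = state.integral + error * dt
    if gains.ki > 0:
        cap = config.integral_limit / gains.ki
        integral = max(-cap, min(cap, integral))
    unsat = gains.kp * error + gains.ki * integral + gains.kd * derivative
    command = max(-config.output_limit, min(config.output_limit, unsat))
    if unsat != command and unsat * error > 0:
        # saturated and error would deepen it: keep the old integral
        integral = state.integral

    new_state = ControllerState(integral=integral, previous_error=error,
                                previous_measured=measured, initialized=True)
    return command, new_state


def arbitrate(command: float, pwm_max: float = float(C.PWM_MAX)) -> PumpCommand:
    """Split a signed command into exclusive air / suction duties."""
    if abs(command) > pwm_max:
        raise ValueError(f"command {command} outside [-{pwm_max}, {pwm_max}]")
    if command > 0:
        return PumpCommand(air_pwm=command, suction_pwm=0.0)
    if command < 0:
        return PumpCommand(air_pwm=0.0, suction_pwm=-command)
    return PumpCommand()
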