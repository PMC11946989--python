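"""Lumped-parameter gas model of the pressurized cavity and its pumps.

The cavity (acrylic chamber, silicone upper-GI simulator, or excised
porcine stomach) is treated as a single isothermal ideal-gas compartment.
Its wall may be distensible: volume follows ``V = V0 + C * P_rel`` where
``C`` is the compliance in mL/mmHg (0 for a rigid chamber).  Pumps are
metered at atmospheric pressure (their free-flow rating), so conservation
of gas amount gives

    d(P_abs * V) = P_atm * Q_net * dt

which, with the compliant volume law, yields the per-step pressure update

    dP_rel = P_atm * Q_net * dt / (V + C * P_abs).

A linear PWM-to-flow map with an optional deadband models the diaphragm
pumps; an optional proportional leak drains ``leak_coefficient * P_rel``
(atmospheric-referenced mL/s) each step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import constants as C


@dataclass(frozen=True)
class PlantConfig:
    """Physical parameters of the cavity and its pumps.

    Parameters
    ----------
    base_volume : float
        Resting gas volume at zero gauge pressure, mL.
    atmospheric_pressure : float
        Ambient absolute pressure, mmHg.
    compliance : float
        Wall distensibility, mL/mmHg; 0 means rigid.
    leak_coefficient : float
        Proportional leak, mL/(s·mmHg) of gauge pressure.
    pump_max_flow : float
        Free flow at full PWM, mL/s.
    pwm_max : int
        Full-scale PWM count.
    pump_deadband_pwm : float
        Commands with magnitude at or below this produce no flow.
    flow_restriction : float
        Fraction of the free-flow rating actually delivered into the
        cavity.  1.0 means direct tubing (the bench calibration chamber);
        rig presets use 0.1 to model the hydraulic resistance of the
        ~2 m endoscope working channel and Y-splitter, which brings the
        full-speed closed-loop slew to the few-mmHg/s scale observed on
        the bench.
    """

    base_volume: float = C.DEFAULT_BASE_VOLUME_ML
    atmospheric_pressure: float = C.ATMOSPHERIC_PRESSURE_MMHG
    compliance: float = 0.0
    leak_coefficient: float = 0.0
    pump_max_flow: float = C.PUMP_FREE_FLOW_ML_S
    pwm_max: int = C.PWM_MAX
    pump_deadband_pwm: float = 0.0
    flow_restriction: float = 1.0

    def __post_init__(self) -> None:
        if self.base_volume <= 0:
            raise ValueError("base_volume must be positive")
        if self.compliance < 0:
            raise ValueError("compliance must be non-negative")
        if self.leak_coefficient < 0:
            raise ValueError("leak_coefficient must be non-negative")
        if self.pump_max_flow <= 0:
            raise ValueError("pump_max_flow must be positive")
        if not (isinstance(self.pwm_max, int) and self.pwm_max > 0):
            raise ValueError("pwm_max must be a positive integer")
        if not 0 <= self.pump_deadband_pwm < self.pwm_max:
            raise ValueError("pump_deadband_pwm must lie in [0, pwm_max)")
        if not 0 < self.flow_restriction <= 1:
            raise ValueError("flow_restriction must lie in (0, 1]")


@dataclass(frozen=True)
class PlantState:
    """Instantaneous state of the cavity: gauge pressure, volume, clock."""

    relative_pressure: float
    gas_volume: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.gas_volume <= 0:
            raise ValueError("gas_volume must be positive")


#: Named cavity presets; compliance values are order-of-magnitude choices
#: (rigid acrylic; stiff silicone; distensible porcine tissue).
PRESETS: dict[str, PlantConfig] = {
    "acrylic": PlantConfig(compliance=0.0),
    "gi_simulator": PlantConfig(compliance=2.0, flow_restriction=0.1),
    "porcine": PlantConfig(compliance=30.0, flow_restriction=0.1),
}


def make_state(config: PlantConfig, relative_pressure: float = 0.0,
               time: float = 0.0) -> PlantState:
    """Build a consistent state at the given gauge pressure."""
    volume = config.base_volume + config.compliance * relative_pressure
    return PlantState(relative_pressure=relative_pressure,
                      gas_volume=volume, time=time)


def pump_flow(command: float, config: PlantConfig) -> float:
    """Signed volumetric flow (mL/s, atmospheric-referenced) for a signed
    PWM command; positive commands insufflate, negative ones suck.

    The map is linear above the deadband and saturates at
    ``pump_max_flow`` for ``|command| == pwm_max``.
    """
    if abs(command) > config.pwm_max:
        raise ValueError(
            f"command {command} outside [-{config.pwm_max}, {config.pwm_max}]")
    magnitude = abs(command)
    if magnitude <= config.pump_deadband_pwm:
        return 0.0
    span = config.pwm_max - config.pump_deadband_pwm
    frac = (magnitude - config.pump_deadband_pwm) / span
    flow = frac * config.pump_max_flow * config.flow_restriction
    return flow if command > 0 else -flow


def step_plant(state: PlantState, net_flow_atm: float, dt: float,
               config: PlantConfig) -> PlantState:
    """Advance the cavity one forward-Euler step.

    ``net_flow_atm`` is the net gas delivery in mL/s metered at atmospheric
    pressure (pump inflow positive).  The leak is subtracted here, so the
    caller passes pump/disturbance flow only.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_atm = config.atmospheric_pressure
    p_rel = state.relative_pressure
    p_abs = p_atm + p_rel
    flow = net_flow_atm - config.leak_coefficient * p_rel
    denom = state.gas_volume + config.compliance * p_abs
    dp = p_atm * flow * dt / denom
    new_rel = p_rel + dp
    # suction floor: absolute pressure never below 5% of atmospheric;
    # a compliant wall additionally may not collapse below 5% of V0
    floor = C.MIN_ABSOLUTE_FRACTION * p_atm - p_atm
    if config.compliance > 0:
        collapse = (C.MIN_ABSOLUTE_FRACTION - 1.0) * config.base_volume
        floor = max(floor, collapse / config.compliance)
    if new_rel < floor:
        new_rel = floor
    new_volume = config.base_volume + config.compliance * new_rel
    return replace(state, relative_pressure=new_rel,
                   gas_volume=new_volume, time=state.time + dt)
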