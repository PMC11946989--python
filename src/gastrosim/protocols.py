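"""End-to-end experiment protocols producing analysis-ready logs.

Each protocol wires the plant, sensor, controller and disturbance
generators into the discrete control loop and returns the three-column
log (elapsed time, relative pressure, motor speed).  The loop runs at
the acquisition cadence of 0.0519 s per tick: sense, control, arbitrate,
apply pump and disturbance flows, advance the plant.

Protocols mirror the bench experiments: a suction calibration sweep, a
long open-loop monitoring run, a step-response suite over 19 initial
pressures, cough/belch spike trains, sinusoidal breathing, and random
mixed events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants as C
from .controller import ControllerConfig, ControllerState, pid_step
from .disturbance import (BreathingParams, DisturbanceSchedule, SpikeParams,
                          mixed_schedule, spike_schedule)
from .logio import LogRecord
from .plant import PlantConfig, PRESETS, make_state, pump_flow, step_plant
from .sensor import SensorConfig, read_sensor
from . import analysis

PROTOCOLS = ("calibration_sweep", "long_monitoring", "step_response",
             "spikes", "breathing", "mixed")


def default_loop_sensor() -> SensorConfig:
    """Sensor settings used inside the control loop: calibrated (unit
    gain, zero offset) with short-term electronic noise only."""
    return SensorConfig(noise_sd=C.LOOP_NOISE_SD_MMHG)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one closed-loop run."""

    plant: PlantConfig = field(default_factory=lambda: PRESETS["gi_simulator"])
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    sensor: SensorConfig = field(default_factory=default_loop_sensor)
    schedule: DisturbanceSchedule | None = None
    duration: float = 60.0
    dt: float = C.SAMPLE_INTERVAL_S
    seed: int = 0
    initial_pressure: float = C.SETPOINT_MMHG
    control_start: float = 0.0   # controller disabled before this time
    log_external: bool = False   # third column: external pump vs. command

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class StepResponseResult:
    """Outcome of one step-response cycle."""

    initial_pressure: float
    response_time: float | None
    steady_mean: float
    steady_sd: float
    ci95: tuple[float, float]


def run_closed_loop(config: ExperimentConfig) -> list[LogRecord]:
    """Simulate one closed-loop experiment and return its log.

    Deterministic under a fixed seed.  The breathing waveform (if any)
    is superimposed on the cavity pressure before sensing; cough/belch
    bursts drive the external pump in parallel with the control pumps.
    """
    rng = np.random.default_rng(config.seed)
    plant_cfg = config.plant
    state = make_state(plant_cfg, config.initial_pressure)
    ctrl_state = ControllerState()
    schedule = config.schedule
    atm = plant_cfg.atmospheric_pressure
    n_steps = int(round(config.duration / config.dt))
    records: list[LogRecord] = []
    for k in range(n_steps):
        t = k * config.dt
        offset = schedule.pressure_offset(t) if schedule else 0.0
        true_rel = state.relative_pressure + offset
        sample = read_sensor(atm + true_rel, t, config.sensor, rng)
        measured = sample.relative_pressure
        if t >= config.control_start:
            command, ctrl_state = pid_step(ctrl_state, measured,
                                           config.dt, config.controller)
        else:
            command = 0.0
        ext_pwm = schedule.external_pwm(t) if schedule else 0.0
        flow = pump_flow(command, plant_cfg) + pump_flow(ext_pwm, plant_cfg)
        state = step_plant(state, flow, config.dt, plant_cfg)
        records.append(LogRecord(
            elapsed_time=t, relative_pressure=measured,
            motor_speed=ext_pwm if config.log_external else command))
    return records


def run_calibration_sweep(levels=C.CALIBRATION_LEVELS_MMHG,
                          stabilize: float = C.CALIBRATION_STABILIZE_S,
                          n_avg: int = C.CALIBRATION_N_AVG,
                          sensor: SensorConfig | None = None,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Suction-sweep calibration table.

    For each gauge level the sensor is sampled through a stabilization
    period and the final ``n_avg`` readings are averaged.  The sensor's
    affine error model is applied on the gauge (relative) scale, so the
    fitted slope/intercept are directly comparable to the injected
    gain/offset.  Returns a table with columns ``gauge_mmHg`` and
    ``mean_reading_mmHg``.
    """
    if n_avg < 1:
        raise ValueError("n_avg must be at least 1")
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if sensor is None:
        sensor = SensorConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    gauge_sensor = replace(sensor, zero_reference=0.0)
    n_settle = max(n_avg, int(round(stabilize / sensor.sample_interval)))
    rows = []
    t = 0.0
    for level in levels:
        readings = []
        for _ in range(n_settle):
            s = read_sensor(level, t, gauge_sensor, rng)
            readings.append(s.relative_pressure)
            t += sensor.sample_interval
        rows.append((level, float(np.mean(readings[-n_avg:]))))
    return pd.DataFrame(rows, columns=["gauge_mmHg", "mean_reading_mmHg"])


def step_suite_pressures() -> np.ndarray:
    """The 19 default initial gauge pressures, evenly spaced between the
    lowest (3.8 mmHg) and highest (23.6 mmHg) bench values."""
    return np.linspace(C.STEP_SUITE_MIN_MMHG, C.STEP_SUITE_MAX_MMHG,
                       C.STEP_SUITE_SIZE)


def run_step_response_suite(initial_pressures=None,
                            config: ExperimentConfig | None = None
                            ) -> list[StepResponseResult]:
    """Step-response protocol over a list of initial pressures.

    Each cycle pre-pressurizes the cavity, holds it uncontrolled for
    20 s, then enables the controller until 60 s total.  The response
    time is the moving-average-of-5 criterion measured from activation;
    steady statistics cover the post-response segment.
    """
    if initial_pressures is None:
        initial_pressures = step_suite_pressures()
    initial_pressures = list(initial_pressures)
    if not initial_pressures:
        raise ValueError("initial_pressures must be non-empty")
    if config is None:
        config = ExperimentConfig()
    results: list[StepResponseResult] = []
    setpoint = config.controller.setpoint
    for i, p0 in enumerate(initial_pressures):
        run_cfg = replace(config, duration=C.STEP_TOTAL_S,
                          control_start=C.STEP_STABILIZE_S,
                          initial_pressure=float(p0),
                          seed=config.seed + i, log_external=False)
        log = run_closed_loop(run_cfg)
        active = [r for r in log if r.elapsed_time >= C.STEP_STABILIZE_S]
        rt = analysis.response_time_step(active, setpoint)
        if rt is None:
            steady = active[len(active) // 2:]
        else:
            steady = [r for r in active
                      if r.elapsed_time - active[0].elapsed_time >= rt]
        summ = analysis.summarize_steady_state(steady, setpoint)
        results.append(StepResponseResult(
            initial_pressure=float(p0), response_time=rt,
            steady_mean=summ.mean, steady_sd=summ.sd, ci95=summ.ci95))
    return results


@dataclass(frozen=True)
class MonitoringSummary:
    """Long-run open-loop monitoring overview (count, pressure stats,
    logging-interval stats)."""

    count: int
    mean_pressure: float
    sd_pressure: float
    mean_dt: float
    sd_dt: float


def run_long_monitoring(duration: float,
                        sensor: SensorConfig | None = None,
                        rng: np.random.Generator | None = None,
                        dt_jitter_sd: float = C.SAMPLE_JITTER_SD_S
                        ) -> tuple[MonitoringSummary, list[LogRecord]]:
    """Open-loop ambient logging with timestamp jitter.

    Samples relative pressure around zero at the nominal cadence with
    Gaussian interval jitter; the record is truncated at exactly
    ``duration`` seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sensor is None:
        sensor = SensorConfig(noise_sd=C.MONITOR_NOISE_SD_MMHG)
    if rng is None:
        rng = np.random.default_rng(0)
    records: list[LogRecord] = []
    t = 0.0
    atm = C.ATMOSPHERIC_PRESSURE_MMHG
    while t <= duration:
        s = read_sensor(atm + (sensor.zero_reference - atm), t, sensor, rng)
        records.append(LogRecord(t, s.relative_pressure, 0.0))
        step = sensor.sample_interval
        if dt_jitter_sd > 0:
            step = max(1e-4, step + float(rng.normal(0.0, dt_jitter_sd)))
        t += step
    times = np.array([r.elapsed_time for r in records])
    pressures = np.array([r.relative_pressure for r in records])
    dts = np.diff(times)
    summary = MonitoringSummary(
        count=len(records),
        mean_pressure=float(np.mean(pressures)),
        sd_pressure=float(np.std(pressures, ddof=1)),
        mean_dt=float(np.mean(dts)) if dts.size else float("nan"),
        sd_dt=float(np.std(dts, ddof=1)) if dts.size > 1 else float("nan"))
    return summary, records


# --- Named protocol builders ------------------------------------------------

def breathing_config(duration: float = C.BREATHING_DURATION_S,
                     seed: int = 0, **overrides) -> ExperimentConfig:
    """Breathing protocol: start uninflated, regulate against a +/-2 mmHg,
    16 cycles/min sinusoid for 10 min."""
    sched = DisturbanceSchedule(breathing=BreathingParams(duration=duration))
    return ExperimentConfig(schedule=sched, duration=duration, seed=seed,
                            initial_pressure=0.0, **overrides)


def spike_config(kind: str = "cough", start: float = 5.0,
                 seed: int = 0, **overrides) -> ExperimentConfig:
    """Cough or belch protocol: settle at the setpoint, then 10 maximum-
    speed external bursts of 0.5 s, each followed by 10 s of monitoring."""
    params = SpikeParams(kind=kind)
    sched = spike_schedule(params, start=start)
    duration = start + params.count * (params.spike_duration + params.gap) + 5.0
    return ExperimentConfig(schedule=sched, duration=duration, seed=seed,
                            log_external=True, **overrides)


def mixed_config(duration: float = C.BREATHING_DURATION_S,
                 n_cough: int = C.SPIKE_COUNT, n_belch: int = C.SPIKE_COUNT,
                 seed: int = 0, **overrides) -> ExperimentConfig:
    """Random cough/belch events during continuous breathing."""
    rng = np.random.default_rng(seed + 1)
    sched = mixed_schedule(duration, n_cough, n_belch, SpikeParams(), rng,
                           BreathingParams(duration=duration))
    return ExperimentConfig(schedule=sched, duration=duration, seed=seed,
                            initial_pressure=0.0, log_external=True,
                            **overrides)
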