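"""Piezoresistive pressure-sensor emulation and affine calibration.

The sensor model is affine-plus-noise: a raw reading is
``gain * P_true + offset + drift_rate * t/3600 + N(0, noise_sd)``.
Calibration against a reference gauge fits the inverse map by ordinary
least squares (gauge regressed on raw reading), so applying the fitted
line to a raw reading yields a corrected pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import constants as C


@dataclass(frozen=True)
class SensorConfig:
    """Affine sensor error model plus sampling cadence.

    ``zero_reference`` is the absolute pressure (mmHg) that reads as
    relative zero; it defaults to atmospheric and can be re-set at any
    anatomical reference the operator chooses.
    """

    true_gain: float = 1.0
    true_offset: float = 0.0
    noise_sd: float = 0.0
    drift_rate: float = 0.0  # mmHg per hour
    sample_interval: float = C.SAMPLE_INTERVAL_S
    zero_reference: float = C.ATMOSPHERIC_PRESSURE_MMHG

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")


@dataclass(frozen=True)
class PressureSample:
    """One sensor reading: absolute and zero-referenced relative pressure."""

    time: float
    absolute_pressure: float
    relative_pressure: float


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line mapping raw reading to reference-gauge pressure."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def read_sensor(true_pressure: float, t: float, config: SensorConfig,
                rng: np.random.Generator) -> PressureSample:
    """Sample the sensor at absolute pressure ``true_pressure`` (mmHg)."""
    reading = (config.true_gain * true_pressure + config.true_offset
               + config.drift_rate * t / 3600.0)
    if config.noise_sd > 0:
        reading += rng.normal(0.0, config.noise_sd)
    return PressureSample(time=t, absolute_pressure=reading,
                          relative_pressure=reading - config.zero_reference)


def fit_calibration(sensor_readings, gauge_values) -> CalibrationFit:
    """Least-squares calibration of raw readings against gauge truth.

    Regresses gauge on reading, so :func:`apply_calibration` maps a raw
    reading to a corrected pressure.  ``r_squared`` is the squared Pearson
    correlation of the pairs.
    """
    x = np.asarray(sensor_readings, dtype=float)
    y = np.asarray(gauge_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("readings and gauge values must be equal-length 1-D")
    if x.size < 2:
        raise ValueError("calibration needs at least 2 points")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("degenerate calibration data: no spread")
    res = stats.linregress(x, y)
    # R^2 via the residual sum of squares so that exactly-affine data
    # yields exactly 1.0 (1 - eps collapses to 1.0 in double precision)
    resid = y - (res.slope * x + res.intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CalibrationFit(slope=float(res.slope),
                          intercept=float(res.intercept),
                          r_squared=1.0 - ss_res / ss_tot,
                          n_points=int(x.size))


@dataclass(frozen=True)
class SensorModelFit:
    """Forward regression of readings on gauge truth: estimates of the
    sensor's affine gain/offset with their standard errors."""

    gain: float
    offset: float
    gain_se: float
    offset_se: float
    r_squared: float


def fit_sensor_model(gauge_values, sensor_readings) -> SensorModelFit:
    """Estimate the sensor's gain and offset (with SEs) by OLS of the
    readings on the reference gauge values."""
    x = np.asarray(gauge_values, dtype=float)
    y = np.asarray(sensor_readings, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired points")
    res = stats.linregress(x, y)
    return SensorModelFit(gain=float(res.slope), offset=float(res.intercept),
                          gain_se=float(res.stderr),
                          offset_se=float(res.intercept_stderr),
                          r_squared=float(res.rvalue) ** 2)


def apply_calibration(raw, fit: CalibrationFit):
    """Corrected pressure ``slope * raw + intercept`` (scalar or array)."""
    if np.ndim(raw):
        return fit.slope * np.asarray(raw, dtype=float) + fit.intercept
    return fit.slope * raw + fit.intercept


def set_zero_reference(samples, at: float) -> list[PressureSample]:
    """Re-zero a stream of samples at absolute pressure ``at`` (mmHg)."""
    return [PressureSample(time=s.time, absolute_pressure=s.absolute_pressure,
                           relative_pressure=s.absolute_pressure - at)
            for s in samples]
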