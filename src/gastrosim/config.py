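"""Experiment configuration files (YAML, with JSON accepted).

A configuration file describes one experiment::

    protocol: breathing          # calibration_sweep | long_monitoring |
                                 # step_response | spikes | breathing | mixed
    duration: 600                # s (protocol-dependent default otherwise)
    dt: 0.0519                   # s
    seed: 1
    initial_pressure: 0.0        # mmHg gauge
    plant:
      preset: gi_simulator       # acrylic | gi_simulator | porcine
      compliance: 2.0            # any PlantConfig field overrides the preset
    controller:
      setpoint: 10.0             # any ControllerConfig / GainSet field
      aggressive: {kp: 40.0, ki: 10.05, kd: 20.0}
      conservative: {kp: 4.0, ki: 10.2, kd: 40.0}
    sensor:
      noise_sd: 0.01             # any SensorConfig field
    disturbance:
      preset: cough              # cough | belch | breathing | mixed
      count: 10                  # spike / breathing parameter overrides

Unknown keys raise an error rather than being silently ignored.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .controller import ControllerConfig, GainSet
from .plant import PlantConfig, PRESETS
from .sensor import SensorConfig

TOP_LEVEL_KEYS = {"protocol", "duration", "dt", "seed", "initial_pressure",
                  "plant", "controller", "sensor", "disturbance"}


class ConfigError(ValueError):
    """Invalid or unreadable experiment configuration."""


def load_config(path) -> dict:
    """Read a YAML or JSON experiment configuration into a dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(data) - TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    return data


def _build(cls, section: dict, what: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown {what} keys {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {what} section: {exc}") from exc


def plant_from_dict(section: dict | None) -> PlantConfig:
    """Plant from a preset name plus field overrides."""
    section = dict(section or {})
    preset = section.pop("preset", "gi_simulator")
    if preset not in PRESETS:
        raise ConfigError(f"unknown plant preset {preset!r}; "
                          f"choose from {sorted(PRESETS)}")
    base = dataclasses.asdict(PRESETS[preset])
    base.update(section)
    return _build(PlantConfig, base, "plant")


def controller_from_dict(section: dict | None) -> ControllerConfig:
    section = dict(section or {})
    for name in ("aggressive", "conservative"):
        if name in section:
            section[name] = _build(GainSet, dict(section[name]),
                                   f"{name} gains")
    return _build(ControllerConfig, section, "controller")


def sensor_from_dict(section: dict | None) -> SensorConfig:
    return _build(SensorConfig, dict(section or {}), "sensor")
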