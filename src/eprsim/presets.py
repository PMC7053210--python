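"""The six shipped simulation presets and JSON config round-trip.

The presets span the study's contrast scenarios, all other fields at
engine defaults (delay/rate numbers are in relative arbitrary units:
frames and particles-per-event under this engine's interpretation):

=====  ==========================  ==========================  ====  ==========
name   FOV clearance (delay/rate)  ROI clearance (delay/rate)  EPR   mode
=====  ==========================  ==========================  ====  ==========
sim1   250 / 50  (fast)            500 / 25                    off   always_on
sim2   250 / 25                    750 / 10  (slow ROI)        off   always_on
sim3   as sim1                     as sim1                     off   responsive
sim4   as sim2                     as sim2                     off   responsive
sim5   as sim2                     as sim2                     on    always_on
sim6   as sim2                     as sim2                     on    responsive
=====  ==========================  ==========================  ====  ==========
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .engine import ConfigError, SimulationConfig
from .geometry import Geometry, GeometryError

__all__ = ["PRESET_NAMES", "preset", "load_config", "save_config", "config_to_dict"]

SCHEMA_VERSION = 1

_PRESET_OVERRIDES: dict[str, dict] = {
    "sim1": {"fov_delay": 250, "fov_rate": 50, "roi_delay": 500, "roi_rate": 25},
    "sim2": {"fov_delay": 250, "fov_rate": 25, "roi_delay": 750, "roi_rate": 10},
}
_PRESET_OVERRIDES["sim3"] = {**_PRESET_OVERRIDES["sim1"], "mode": "responsive"}
_PRESET_OVERRIDES["sim4"] = {**_PRESET_OVERRIDES["sim2"], "mode": "responsive"}
_PRESET_OVERRIDES["sim5"] = {**_PRESET_OVERRIDES["sim2"], "epr_enabled": True}
_PRESET_OVERRIDES["sim6"] = {**_PRESET_OVERRIDES["sim2"], "epr_enabled": True,
                             "mode": "responsive"}

PRESET_NAMES = tuple(sorted(_PRESET_OVERRIDES))


def preset(name: str) -> SimulationConfig:
    """The named preset as a fully validated configuration."""
    key = name.lower().replace("-", "")
    if key not in _PRESET_OVERRIDES:
        raise ConfigError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    return SimulationConfig(**_PRESET_OVERRIDES[key]).validate()


# ---------------------------------------------------------------------------
# JSON round-trip

_GEOM_FIELDS = [f.name for f in dataclasses.fields(Geometry)]
_CONFIG_FIELDS = [f.name for f in dataclasses.fields(SimulationConfig) if f.name != "geometry"]


def config_to_dict(config: SimulationConfig) -> dict:
    geom = {name: getattr(config.geometry, name) for name in _GEOM_FIELDS}
    geom = {k: list(v) if isinstance(v, tuple) else v for k, v in geom.items()}
    out = {name: getattr(config, name) for name in _CONFIG_FIELDS}
    out["geometry"] = geom
    out["schema_version"] = SCHEMA_VERSION
    return out


def save_config(config: SimulationConfig, path) -> None:
    """Write the full config as canonical JSON (sorted keys, 2-space indent).

    Save -> load -> save is byte-identical.
    """
    config.validate()
    payload = json.dumps(config_to_dict(config), sort_keys=True, indent=2) + "\n"
    Path(path).write_text(payload)


def _check_keys(given: dict, expected: list[str], context: str) -> None:
    unknown = sorted(set(given) - set(expected))
    if unknown:
        raise ConfigError(f"{context}: unknown key(s): {', '.join(unknown)}")
    missing = sorted(set(expected) - set(given))
    if missing:
        raise ConfigError(f"{context}: missing key(s): {', '.join(missing)}")


def load_config(path) -> SimulationConfig:
    """Load and validate a JSON config written by :func:`save_config`.

    The schema is strict: every field must be present (including ``seed``)
    and unknown keys are rejected, so stale or misspelled settings never
    pass silently.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a JSON object")
    _check_keys(raw, _CONFIG_FIELDS + ["geometry", "schema_version"], str(path))
    if raw["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: schema_version: expected {SCHEMA_VERSION}, got {raw['schema_version']}"
        )
    geom_raw = raw["geometry"]
    if not isinstance(geom_raw, dict):
        raise ConfigError(f"{path}: geometry: must be a JSON object")
    _check_keys(geom_raw, _GEOM_FIELDS, f"{path}: geometry")
    try:
        geometry = Geometry(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in geom_raw.items()})
    except GeometryError as exc:
        raise ConfigError(f"{path}: geometry: {exc}") from exc
    kwargs = {k: raw[k] for k in _CONFIG_FIELDS}
    return SimulationConfig(geometry=geometry, **kwargs).validate()
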