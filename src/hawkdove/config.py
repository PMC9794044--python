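"""Reading and writing run configurations.

The on-disk format is a flat TOML file whose keys are exactly the
:class:`~hawkdove.engine.SimulationConfig` field names (``b``, ``c``,
``T``, ``L``, ``L_SD``, ``m_r``, ``d``, ``GS_min``, ``GS_max``,
``N_max``, ``N_0``, ...). Every key is optional; omitted keys take the
standard fixed values, so an empty file is a valid base configuration.
"""

from __future__ import annotations

import tomllib
from dataclasses import fields
from pathlib import Path

from .engine import SimulationConfig

__all__ = ["load_config", "loads_config", "write_config", "dumps_config"]

_FIELD_NAMES = tuple(f.name for f in fields(SimulationConfig))


def loads_config(text: str) -> SimulationConfig:
    """Parse a TOML string into a validated config."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ValueError(f"config is not valid TOML: {exc}") from exc
    unknown = sorted(set(data) - set(_FIELD_NAMES))
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return SimulationConfig(**data)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a config file; all omitted keys default to the fixed
    parameter values. Invalid values raise ``ValueError`` naming the
    offending field."""
    return loads_config(Path(path).read_text())


def _format_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return repr(value)


def dumps_config(config: SimulationConfig) -> str:
    lines = [
        f"{name} = {_format_value(getattr(config, name))}"
        for name in _FIELD_NAMES
    ]
    return "\n".join(lines) + "\n"


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as flat TOML; round-trips exactly through
    :func:`load_config`."""
    Path(path).write_text(dumps_config(config))
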