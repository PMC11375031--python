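"""Structured run configuration (YAML/JSON) with unit-suffixed keys.

Every physical quantity in a config carries its unit in the key name
(``total_flow_rate_ul_h``, ``ipt_max_ms``, ...), so a mis-scaled value fails
validation instead of silently corrupting concentration or flux math.
Unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from . import physics
from .bursts import BurstSearchParams
from .chip import ChipGeometry, FlowSettings, SolverOptions
from .exceptions import InvalidParameterError
from .synthetic import AcquisitionSpec

_SECTIONS = {
    "geometry": ChipGeometry,
    "flow": FlowSettings,
    "conditions": physics.SolventConditions,
    "solver": SolverOptions,
    "burst_search": BurstSearchParams,
    "acquisition": AcquisitionSpec,
}


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(data, dict):
        raise InvalidParameterError("config root must be a mapping")
    return data


def build_section(data: dict, section: str):
    """Instantiate one config section, rejecting unknown keys."""
    cls = _SECTIONS[section]
    kwargs = data.get(section, {}) or {}
    valid = set(cls.__dataclass_fields__)
    unknown = set(kwargs) - valid
    if unknown:
        raise InvalidParameterError(
            f"unknown keys in [{section}]: {sorted(unknown)}; valid: {sorted(valid)}")
    return cls(**kwargs)
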