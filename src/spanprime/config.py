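"""Run configuration: defaults <- YAML config file <- CLI overrides.

Dotted keys (``primer.tm_min``, ``ehtpcr.max_mismatches``, ...) address
fields of the parameter dataclasses.  Every effective parameter is echoed
into the run manifest so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Any

import yaml

from .eht_pcr import EHTPCRParams
from .gene_structure import JunctionParams
from .ortholog_align import AlignParams
from .primer_design import PrimerParams
from .simulate import SimParams


@dataclass
class RunConfig:
    primer: PrimerParams = field(default_factory=PrimerParams)
    align: AlignParams = field(default_factory=AlignParams)
    junction: JunctionParams = field(default_factory=JunctionParams)
    ehtpcr: EHTPCRParams = field(default_factory=EHTPCRParams)
    sim: SimParams = field(default_factory=SimParams)
    max_mismatches_per_block: int = 3
    page_size: int = 60
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTIONS = ("primer", "align", "junction", "ehtpcr", "sim")


def _coerce(value: str, current: Any) -> Any:
    if isinstance(current, bool):
        return str(value).lower() in ("1", "true", "yes", "on")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(value)
    if isinstance(current, float):
        return float(value)
    if isinstance(current, tuple):
        parts = str(value).replace(",", " ").split()
        return tuple(type(current[0])(p) for p in parts)
    return value


def apply_overrides(cfg: RunConfig, overrides: dict[str, Any]) -> RunConfig:
    """Apply ``{"primer.tm_min": "54", "seed": 7}``-style dotted overrides."""
    for key, value in overrides.items():
        if "." in key:
            section, name = key.split(".", 1)
            if section not in _SECTIONS:
                raise KeyError(f"unknown config section {section!r}")
            params = getattr(cfg, section)
            if not hasattr(params, name):
                raise KeyError(f"unknown parameter {key!r}")
            coerced = _coerce(value, getattr(params, name))
            setattr(cfg, section, replace(params, **{name: coerced}))
        else:
            if not hasattr(cfg, key):
                raise KeyError(f"unknown parameter {key!r}")
            setattr(cfg, key, _coerce(value, getattr(cfg, key)))
    return cfg


def load_config(path: str | None = None, overrides: dict[str, Any] | None = None) -> RunConfig:
    cfg = RunConfig()
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat: dict[str, Any] = {}
        for key, value in data.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    flat[f"{key}.{sub}"] = v
            else:
                flat[key] = value
        apply_overrides(cfg, flat)
    if overrides:
        apply_overrides(cfg, overrides)
    return cfg
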