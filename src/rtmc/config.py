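"""Configuration handling: defaults, YAML load, flat snapshot."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .exceptions import ParameterError

__all__ = ["RtmcConfig", "load_config"]


@dataclass
class RtmcConfig:
    """All pipeline tunables with their defaults.

    YAML files use nested sections (``filter:``, ``register:``,
    ``template:``, ``output:``) whose keys map onto these fields.
    """

    # filter.*
    neuron_diameter: float = 10.0
    sigma: float | None = None          # null = neuron_diameter / 2
    size_factor: float = 3.0
    # register.*
    max_shift: int = 20
    min_overlap: float = 0.5
    eps: float = 1e-12
    # template.*
    k: int = 200
    prerecorded_path: str | None = None
    # output.*
    float_out: bool = False
    frame_rate: float = 20.0

    def snapshot(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "filter": {"neuron_diameter", "sigma", "size_factor"},
    "register": {"max_shift", "min_overlap", "eps"},
    "template": {"k", "prerecorded_path"},
    "output": {"float_out", "frame_rate"},
}


def load_config(path: str | None = None, overrides: dict | None = None) -> RtmcConfig:
    """Load a nested-YAML config; unknown keys raise a parameter error."""
    cfg = RtmcConfig()
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for section, keys in _SECTIONS.items():
        sub = data.pop(section, {}) or {}
        for key, value in sub.items():
            if key not in keys:
                raise ParameterError(f"unknown config key {section}.{key}")
            setattr(cfg, key, value)
    if data:
        raise ParameterError(f"unknown config section(s): {sorted(data)}")
    for key, value in (overrides or {}).items():
        if not hasattr(cfg, key):
            raise ParameterError(f"unknown config override {key}")
        setattr(cfg, key, value)
    return cfg
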