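"""Structured-text run configuration (YAML, with dotted or nested sections)."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .genetics import FounderRanges
from .landscape import EcoParams
from .mating import MatingConfig
from .epoch import EpochConfig

__all__ = ["load_config", "build_epoch_config", "default_config_dict"]

_SECTIONS = {"eco": EcoParams, "mating": MatingConfig, "founder_ranges": FounderRanges}
_EPOCH_KEYS = {
    f.name for f in dataclasses.fields(EpochConfig)
    if f.name not in ("eco", "mating", "founder_ranges")
}


def _nest(flat: dict[str, Any]) -> dict[str, Any]:
    """Expand dotted keys (``eco.r: 0.2``) into nested sections."""
    out: dict[str, Any] = {}
    for key, value in flat.items():
        if isinstance(key, str) and "." in key:
            section, sub = key.split(".", 1)
            out.setdefault(section, {})
            if not isinstance(out[section], dict):
                raise ValueError(f"conflicting config key {key!r}")
            out[section][sub] = value
        elif isinstance(value, dict):
            out.setdefault(key, {})
            out[key].update(value)
        else:
            out[key] = value
    return out


def build_epoch_config(raw: dict[str, Any] | None, **overrides: Any) -> EpochConfig:
    """Materialize an EpochConfig from a parsed config mapping plus overrides.

    Unknown keys are rejected rather than ignored so typos cannot silently
    fall back to defaults.
    """
    data = _nest(dict(raw or {}))
    data.update({k: v for k, v in overrides.items() if v is not None})

    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        section_data = data.pop(section, {})
        if not isinstance(section_data, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section_data) - valid
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        for key in ("alpha", "delta", "rho"):
            if section == "founder_ranges" and key in section_data:
                section_data[key] = tuple(section_data[key])
        kwargs[section] = cls(**section_data)

    unknown = set(data) - _EPOCH_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(data)
    return EpochConfig(**kwargs)


def load_config(path: str | Path | None, **overrides: Any) -> EpochConfig:
    raw = None
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
    return build_epoch_config(raw, **overrides)


def default_config_dict(config: EpochConfig | None = None) -> dict[str, Any]:
    """All parameters, defaults materialized, as a nested plain-data mapping."""
    cfg = config or EpochConfig()
    out = {
        name: getattr(cfg, name)
        for name in sorted(_EPOCH_KEYS)
    }
    out["eco"] = dataclasses.asdict(cfg.eco)
    out["mating"] = dataclasses.asdict(cfg.mating)
    out["founder_ranges"] = {
        "alpha": list(cfg.founder_ranges.alpha),
        "delta": list(cfg.founder_ranges.delta),
        "rho": list(cfg.founder_ranges.rho),
        "m_init": cfg.founder_ranges.m_init,
    }
    return out


def dump_yaml(data: dict[str, Any]) -> str:
    return yaml.safe_dump(data, sort_keys=True, default_flow_style=False)
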