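"""Structured configuration: YAML in, validated parameter objects out.

A configuration has four sections — ``lifecycle``, ``genetics``,
``release`` and ``simulation`` — each optional; missing fields take the
package defaults (the headline study conditions: 10,000-adult
equilibrium, 90% cutting per allele, maternal deposition in 90% of
embryos, transgenic male mating weight 0.75).  Unknown keys are
rejected, naming the offending key, so typos cannot silently revert a
parameter to its default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .inheritance import GeneticParams, System
from .lifecycle import LifeHistoryParams
from .release import ReleaseScheme

__all__ = ["SimulationParams", "FullConfig", "load_config", "dump_config", "default_config"]


class ConfigError(ValueError):
    """A configuration problem, carrying the path to the offending field."""


@dataclass(frozen=True)
class SimulationParams:
    """Run-level settings: horizon, replicate count, master seed."""

    horizon_days: int = 6 * 365
    replicates: int = 30
    seed: int = 1
    stochastic: bool = True
    suppression_denominator: str = "adults"  # or "females"

    def __post_init__(self) -> None:
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.suppression_denominator not in ("adults", "females"):
            raise ValueError("suppression_denominator must be 'adults' or 'females'")


@dataclass(frozen=True)
class FullConfig:
    lifecycle: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    genetics: GeneticParams = field(default_factory=GeneticParams)
    release: ReleaseScheme = field(default_factory=lambda: ReleaseScheme(0, 0.0))
    simulation: SimulationParams = field(default_factory=SimulationParams)


_SECTIONS = {
    "lifecycle": LifeHistoryParams,
    "genetics": GeneticParams,
    "release": ReleaseScheme,
    "simulation": SimulationParams,
}


def _build_section(name: str, cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {name}.{key}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        # find the offending field for a precise error path
        for key, value in data.items():
            try:
                cls(**{key: value})
            except (TypeError, ValueError):
                raise ConfigError(f"invalid value for {name}.{key}: {exc}") from exc
        raise ConfigError(f"invalid section {name}: {exc}") from exc


def load_config(source) -> FullConfig:
    """Load and validate a YAML configuration.

    ``source`` is a path or an open file object; an empty document yields
    the full default configuration.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh.read())
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the configuration must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section {sorted(unknown)[0]}")
    sections = {}
    for name, cls in _SECTIONS.items():
        data = raw.get(name) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"section {name} must be a mapping")
        sections[name] = _build_section(name, cls, dict(data))
    return FullConfig(**sections)


def _as_dict(cfg: FullConfig) -> dict:
    out = {}
    for name in _SECTIONS:
        section = dataclasses.asdict(getattr(cfg, name))
        for k, v in section.items():
            if isinstance(v, System):
                section[k] = v.value
        out[name] = section
    return out


def dump_config(cfg: FullConfig, stream=None) -> str:
    """Serialise a configuration (all fields explicit) to YAML."""
    text = yaml.safe_dump(_as_dict(cfg), sort_keys=True)
    if stream is not None:
        stream.write(text)
    return text


def default_config() -> FullConfig:
    return FullConfig()
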