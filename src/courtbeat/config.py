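"""One-document run configuration for the command-line pipeline.

A ``RunConfig`` aggregates every module's tunable parameters plus the
global seed, and round-trips through a single YAML/JSON document.
Unknown keys are rejected so typos fail loudly instead of silently
reverting to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from courtbeat.dsp import FilterSpec
from courtbeat.features import FeatureConfig
from courtbeat.models import EnsembleConfig, ImpactModelConfig
from courtbeat.peaks import PeakConfig
from courtbeat.synthcourt import BankSpec


class ConfigError(ValueError):
    """Raised for unknown keys or malformed config documents."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one serializable object."""

    seed: int = 42
    out_dir: str = "."
    k_best: int = 150
    match_tol_s: float = 0.020
    peaks: PeakConfig = field(default_factory=PeakConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    bank: BankSpec = field(default_factory=BankSpec)
    impact_model: ImpactModelConfig = field(default_factory=ImpactModelConfig)
    rebound_model: EnsembleConfig = field(default_factory=EnsembleConfig)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, dict):
            sub_cls = _NESTED.get(name)
            if sub_cls is None:
                raise ConfigError(f"{path}.{name} does not take a mapping")
            kwargs[name] = _build(sub_cls, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config at {path}: {exc}") from exc


_NESTED = {
    "peaks": PeakConfig,
    "filter": FilterSpec,
    "features": FeatureConfig,
    "bank": BankSpec,
    "impact_model": ImpactModelConfig,
    "rebound_model": EnsembleConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) document."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config document must be a mapping")
    return _build(RunConfig, data, "config")


def dump_config(config: RunConfig) -> str:
    """Serialize a RunConfig (all resolved values) to YAML."""
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)


def config_digest(config: RunConfig) -> str:
    import hashlib

    return hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
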