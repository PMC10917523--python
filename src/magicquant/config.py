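"""Run configuration: nested parameter blocks loadable from YAML.

Every parameter has a documented default on its dataclass; unknown keys in a
config file are rejected rather than silently ignored. The effective
configuration can be echoed back to YAML for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .nc_ratio import NCParams
from .puncta import PunctaParams
from .segmentation import SegmentationParams


@dataclass
class SpGFPConfig:
    threshold_frac: float = 0.05
    per_image_max: bool = False
    test: str = "welch"  # or "student" / "paired"
    reference_group: str | None = None


@dataclass
class NCRatioConfig:
    params: NCParams = field(default_factory=NCParams)
    test: str = "welch"
    reference_group: str | None = None


@dataclass
class PunctaConfig:
    params: PunctaParams = field(default_factory=PunctaParams)
    test: str = "welch"


@dataclass
class ChaseConfig:
    test: str = "welch"
    fit: bool = True


@dataclass
class HydropathyConfig:
    window: int = 5
    edge_weight: float = 1.0


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spgfp: SpGFPConfig = field(default_factory=SpGFPConfig)
    ncratio: NCRatioConfig = field(default_factory=NCRatioConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    chase: ChaseConfig = field(default_factory=ChaseConfig)
    hydropathy: HydropathyConfig = field(default_factory=HydropathyConfig)


class ConfigError(ValueError):
    """Raised for unknown keys or malformed config files."""


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        default = getattr(cls(), name) if dataclasses.is_dataclass(cls) else None
        if dataclasses.is_dataclass(default.__class__) and isinstance(value, dict):
            kwargs[name] = _build(default.__class__, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    return _build(RunConfig, raw, "config")


def dump_config(cfg: RunConfig) -> str:
    """Render the effective configuration as YAML (for provenance echoing)."""
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
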