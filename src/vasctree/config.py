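"""Pipeline configuration: one YAML-loadable object gathering every stage's
parameters, validated on load with unknown keys rejected."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import GeometryRuleConfig
from .preprocess import PreprocessConfig

__all__ = ["PipelineConfig", "load_config", "default_config_yaml"]


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    geometry: GeometryRuleConfig = field(default_factory=GeometryRuleConfig)
    qc_min_area: int = 100
    start_delta: float = 20.0
    fd_on_skeleton: bool = False
    fd_offset_average: bool = False
    patch_size: int = 128
    macula_radius_factor: float = 0.6
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "preprocess": dataclasses.asdict(self.preprocess),
            "geometry": dataclasses.asdict(self.geometry),
            "qc_min_area": self.qc_min_area,
            "start_delta": self.start_delta,
            "fd_on_skeleton": self.fd_on_skeleton,
            "fd_offset_average": self.fd_offset_average,
            "patch_size": self.patch_size,
            "macula_radius_factor": self.macula_radius_factor,
            "seed": self.seed,
        }


def _build(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError("unknown %s config keys: %s" % (context, sorted(unknown)))
    return cls(**data)


def load_config(path_or_dict) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file or a dict."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    pre = _build(PreprocessConfig, data.pop("preprocess", {}), "preprocess")
    geom = _build(GeometryRuleConfig, data.pop("geometry", {}), "geometry")
    cfg = _build(PipelineConfig, {"preprocess": pre, "geometry": geom, **data},
                 "pipeline")
    return cfg


def default_config_yaml() -> str:
    """The full default configuration, serialisable as a starting point."""
    return yaml.safe_dump(PipelineConfig().to_dict(), sort_keys=False)
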