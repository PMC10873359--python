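"""Pipeline configuration: a nested dataclass mirroring every CLI flag, loaded
from YAML with strict key checking (unknown keys are rejected, naming the key).

Defaults are the pipeline's standard operating point: 1024 px patches with 30%
overlap and 75% minimum tissue at 20x, 9 color clusters with 15% selection,
nu = 0.05, top-k consensus at k in {1, 3, 5}.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, get_origin

import yaml

from normatlas.atlas import AtlasConfig
from normatlas.mosaic import MosaicConfig
from normatlas.slide_patching import PatchGridConfig
from normatlas.synthetic_data import ClassSpec, FeatureSimConfig


@dataclass
class SearchConfig:
    k_values: tuple[int, ...] = (1, 3, 5)
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.k_values = tuple(int(k) for k in self.k_values)
        if any(k < 1 for k in self.k_values):
            raise ValueError("all k values must be >= 1")


@dataclass
class PipelineConfig:
    """Global seed plus one section per pipeline stage."""

    seed: int = 0
    patching: PatchGridConfig = field(default_factory=PatchGridConfig)
    simulate: FeatureSimConfig = field(default_factory=FeatureSimConfig)
    mosaic: MosaicConfig = field(default_factory=MosaicConfig)
    atlas: AtlasConfig = field(default_factory=AtlasConfig)
    search: SearchConfig = field(default_factory=SearchConfig)


def _build(cls, data: Any, where: str):
    """Instantiate a (possibly nested) dataclass from a mapping, rejecting
    unknown keys."""
    if data is None:
        data = {}
    if dataclasses.is_dataclass(cls):
        if not isinstance(data, dict):
            raise ValueError(f"config section {where or cls.__name__!r} must be a mapping")
        names = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(names)
        if unknown:
            raise ValueError(
                f"unknown config key {sorted(unknown)[0]!r} in section {where or 'root'!r}"
            )
        kwargs = {}
        for key, value in data.items():
            f = names[key]
            ftype = f.type if not isinstance(f.type, str) else None
            target = _nested_dataclass(cls, key)
            if target is not None:
                kwargs[key] = _build(target, value, f"{where}.{key}" if where else key)
            elif key == "classes":
                kwargs[key] = tuple(
                    ClassSpec(**c) if isinstance(c, dict) else ClassSpec(*c) for c in value
                )
            elif isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
    return data


_NESTED = {
    (PipelineConfig, "patching"): PatchGridConfig,
    (PipelineConfig, "simulate"): FeatureSimConfig,
    (PipelineConfig, "mosaic"): MosaicConfig,
    (PipelineConfig, "atlas"): AtlasConfig,
    (PipelineConfig, "search"): SearchConfig,
}


def _nested_dataclass(cls, key: str):
    return _NESTED.get((cls, key))


def pipeline_config_from_dict(data: dict | None) -> PipelineConfig:
    return _build(PipelineConfig, data or {}, "")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML file; unknown keys are an error."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return pipeline_config_from_dict(data)


def config_snapshot(cfg: PipelineConfig) -> dict:
    """A JSON-serializable snapshot of the full configuration."""
    return dataclasses.asdict(cfg)
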