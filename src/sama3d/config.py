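"""Typed run configuration: one YAML file drives an entire pipeline run.

Unknown keys are rejected (typo safety) and numeric fields are range-checked
at load time; a resolved copy of the configuration is written into every
output directory so runs are auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .imgproc import Tier1Config
from .segment import MIN_VOXELS
from .lumen import MIN_LUMEN_VOXELS
from .skeleton import DEFAULT_PRUNE_LENGTH

__all__ = ["RunConfig", "LumenConfig", "SkeletonConfig", "SegmentConfig", "StatsConfig",
           "load_config", "dump_config"]


@dataclass
class SegmentConfig:
    min_voxels: int = MIN_VOXELS
    exclude_border: bool = False

    def validate(self) -> None:
        if self.min_voxels < 1:
            raise ValueError("segment.min_voxels must be >= 1")


@dataclass
class LumenConfig:
    enabled: bool = True
    threshold: float | str = "interior-otsu"
    min_lumen_voxels: int = MIN_LUMEN_VOXELS
    fill_mode: str = "2d"

    def validate(self) -> None:
        if self.min_lumen_voxels < 1:
            raise ValueError("lumen.min_lumen_voxels must be >= 1")
        if self.fill_mode not in ("2d", "3d"):
            raise ValueError("lumen.fill_mode must be '2d' or '3d'")


@dataclass
class SkeletonConfig:
    enabled: bool = True
    prune_length: float = DEFAULT_PRUNE_LENGTH

    def validate(self) -> None:
        if self.prune_length < 0:
            raise ValueError("skeleton.prune_length must be >= 0")


@dataclass
class StatsConfig:
    unit: str = "stack"  # experimental unit: per-stack mean (or 'structure')
    include_lumen: bool = True
    include_branching: bool = True
    parameters: list[str] | None = None

    def validate(self) -> None:
        if self.unit not in ("stack", "structure"):
            raise ValueError("stats.unit must be 'stack' or 'structure'")


@dataclass
class RunConfig:
    input_dir: str = "."
    out_dir: str = "sama3d_out"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    metadata: str | None = None  # CSV: stack, condition, replicate
    seed: int = 0
    verbosity: str = "INFO"
    tier1: Tier1Config = field(default_factory=Tier1Config)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    lumen: LumenConfig = field(default_factory=LumenConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> None:
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers")
        if self.tier1.median_radius < 1 or self.tier1.background_radius < 1:
            raise ValueError("tier1 radii must be >= 1")
        if self.tier1.gaussian_sigma < 0:
            raise ValueError("tier1.gaussian_sigma must be >= 0")
        for sub in (self.segment, self.lumen, self.skeleton, self.stats):
            sub.validate()


def _build(cls, data: dict, path: str = ""):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path or cls.__name__}'")
    return cls(**data)


_SECTIONS = {
    "tier1": Tier1Config,
    "segment": SegmentConfig,
    "lumen": LumenConfig,
    "skeleton": SkeletonConfig,
    "stats": StatsConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    top_fields = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for name, value in raw.items():
        if name in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section '{name}' must be a mapping")
            kwargs[name] = _build(_SECTIONS[name], value, name)
        elif name == "spacing":
            kwargs[name] = tuple(float(v) for v in value)
        else:
            kwargs[name] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration (used for the per-run audit copy)."""
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in fields(obj)
                    if f.name != "denoise_hook"}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(enc(cfg), fh, sort_keys=True)
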