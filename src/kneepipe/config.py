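"""YAML pipeline configuration with validation and round-tripping.

One file drives every stage; unknown keys are rejected with the offending
section.key named, so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detector import CascadeConfig
from .grader import GraderConfig
from .trainer import AugmentConfig, TrainConfig


class ConfigError(ValueError):
    pass


@dataclass
class PreprocessCfg:
    clahe: bool = False


@dataclass
class RoiCfg:
    margin_factor: float = 0.2
    patch_size: int = 128

    def __post_init__(self):
        if self.margin_factor < 0:
            raise ConfigError("roi.margin_factor must be >= 0")
        if self.patch_size < 8:
            raise ConfigError("roi.patch_size must be >= 8")


@dataclass
class MetricsCfg:
    kappa_weighting: str = "quadratic"
    iou_min: float = 0.5

    def __post_init__(self):
        if self.kappa_weighting not in ("none", "linear", "quadratic"):
            raise ConfigError("metrics.kappa_weighting must be none|linear|quadratic")
        if not 0 < self.iou_min <= 1:
            raise ConfigError("metrics.iou_min must be in (0, 1]")


@dataclass
class PipelineConfig:
    seed: int = 0
    preprocess: PreprocessCfg = field(default_factory=PreprocessCfg)
    detector: CascadeConfig = field(default_factory=CascadeConfig)
    roi: RoiCfg = field(default_factory=RoiCfg)
    grader: GraderConfig = field(default_factory=GraderConfig)
    trainer: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricsCfg = field(default_factory=MetricsCfg)


_SECTIONS = {
    "preprocess": PreprocessCfg,
    "detector": CascadeConfig,
    "roi": RoiCfg,
    "grader": GraderConfig,
    "trainer": TrainConfig,
    "metrics": MetricsCfg,
}


def _build(cls, data: dict, section: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown key {section}.{key}")
        ftype = names[key].type
        if key == "augment" and isinstance(value, dict):
            value = _build(AugmentConfig, value, f"{section}.augment")
        elif isinstance(value, list) and "tuple" in str(ftype):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Parse and validate a YAML config; an empty/missing file yields defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key == "seed":
            kwargs["seed"] = int(value)
        elif key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value or {}, key)
        else:
            raise ConfigError(f"unknown key {key}")
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg),
                                         sort_keys=False))
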