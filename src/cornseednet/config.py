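"""Run configuration: nested YAML blocks mapped onto the module dataclasses.

Unknown keys are rejected with the offending field named, so typos never
silently fall back to defaults.  An empty file yields all defaults, and
``dump_config(load_config(p))`` is stable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cnn import ArchitectureSpec, TrainingConfig
from .preprocess import AugmentationSpec
from .segmentation import SegmentationParams
from .synthetic import SceneSpec


@dataclass
class EvaluationOptions:
    jaccard_threshold: float = 0.5
    count_segmentation_misses: bool = True   # include unmatched seeds as FN

    def __post_init__(self):
        if not (0.0 < self.jaccard_threshold <= 1.0):
            raise ValueError("jaccard_threshold must be in (0, 1]")


@dataclass
class RunConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    scene: SceneSpec = field(default_factory=SceneSpec)
    evaluation: EvaluationOptions = field(default_factory=EvaluationOptions)
    paths: dict = field(default_factory=dict)
    rng_seed: int = 0


class ConfigError(ValueError):
    pass


def _build(cls, data, context):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


_BLOCKS = {
    "segmentation": SegmentationParams,
    "augmentation": AugmentationSpec,
    "architecture": ArchitectureSpec,
    "training": TrainingConfig,
    "scene": SceneSpec,
    "evaluation": EvaluationOptions,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(data) - set(_BLOCKS) - {"paths", "rng_seed"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    kwargs = {name: _build(cls, data.get(name), f"{path}:{name}")
              for name, cls in _BLOCKS.items()}
    paths = data.get("paths", {}) or {}
    if not isinstance(paths, dict):
        raise ConfigError(f"{path}:paths: expected a mapping")
    return RunConfig(paths=paths, rng_seed=int(data.get("rng_seed", 0)), **kwargs)


def dump_config(config: RunConfig) -> str:
    """Serialise a RunConfig back to YAML (stable under load/dump round-trip)."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    data = {name: clean(getattr(config, name)) for name in _BLOCKS}
    data["paths"] = dict(config.paths)
    data["rng_seed"] = config.rng_seed
    return yaml.safe_dump(data, sort_keys=True)
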