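"""YAML configuration for the pipeline.

All defaults equal the clinical-protocol values: patch 128, stride 64,
2 context slices, learning rate 1e-4 halved on a 2-epoch plateau, 30
epochs, batch 256, L2 beta 1e-5, percentile window (0.5, 99.5), probability
threshold 0.5, minimum lesion volume 0.02 cc, 3 mm evaluation margin.
Sections: ``preprocess``, ``patch``, ``train``, ``unet``, ``inference``,
``phantom``, ``study``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .experiment import StudyConfig
from .nn import UNetSpec
from .phantom import PhantomSpec
from .training import TrainConfig


@dataclass
class PreprocessConfig:
    bias_mode: str = "n4"
    lower_pct: float = 0.5
    upper_pct: float = 99.5
    gamma_range: tuple[float, float] = (0.8, 1.2)


@dataclass
class PatchConfig:
    size: int = 128
    stride: int = 64
    context_slices: int = 2


@dataclass
class InferenceConfig:
    threshold: float = 0.5
    min_volume_cc: float = 0.02
    margin_mm: float = 3.0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    patch: PatchConfig = field(default_factory=PatchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    unet: UNetSpec = field(default_factory=UNetSpec)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    study: StudyConfig = field(default_factory=StudyConfig)


def _apply(obj, overrides: dict):
    for key, value in overrides.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key {key!r} for {type(obj).__name__}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply(current, value)
        else:
            if isinstance(current, tuple) and isinstance(value, (list, tuple)):
                value = tuple(value)
            setattr(obj, key, value)
    return obj


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and overrides."""
    cfg = PipelineConfig()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        _apply(cfg, data)
    if overrides:
        _apply(cfg, overrides)
    return cfg


def config_hash(cfg) -> str:
    """Stable short hash of a (nested) dataclass config, for provenance."""

    def encode(o):
        if dataclasses.is_dataclass(o):
            return {f.name: encode(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, (list, tuple)):
            return [encode(v) for v in o]
        if isinstance(o, type):
            return o.__name__
        return o

    blob = json.dumps(encode(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
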