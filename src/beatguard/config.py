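"""Structured pipeline configuration with YAML/JSON overrides."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import Hyperparams


@dataclass
class FilterConfig:
    low: float = 0.5
    high: float = 40.0
    order: int = 4
    causal: bool = False


@dataclass
class SegmentationConfig:
    pre: int = 100
    post: int = 156


@dataclass
class FeatureConfig:
    third_wavelet_metric: str = "std"   # or "relative_energy"
    rr_history_len: int = 32
    min_rr_history: int = 16
    sampen_m: int = 2
    sampen_r_factor: float = 0.2


@dataclass
class ModelConfig:
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    smote_k: int = 5
    cv_folds: int = 5
    tuner_backend: str = "random"


@dataclass
class IDSConfig:
    window_s: float = 2.0
    hop_s: float = 1.0
    replay_buffer: int = 5
    tau: float = 0.5


@dataclass
class ExplainConfig:
    top_k: int = 5


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    ids: IDSConfig = field(default_factory=IDSConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a config file (YAML or JSON); missing keys keep their defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
        else json.loads(text)
    if not doc:
        return cfg
    for f in fields(cfg):
        if f.name not in doc:
            continue
        group = getattr(cfg, f.name)
        overrides = doc[f.name] or {}
        for key, value in overrides.items():
            if key == "hyperparams":
                group.hyperparams = Hyperparams(
                    **{**group.hyperparams.as_dict(), **value})
            elif hasattr(group, key):
                setattr(group, key, value)
            else:
                raise KeyError(f"unknown config key {f.name}.{key}")
    return cfg
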