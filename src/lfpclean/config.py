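"""Pipeline configuration: one flat key-value document for every tunable.

Loaded from YAML; unknown keys are rejected so typos fail loudly.  The
canonical-JSON SHA-256 of the configuration is recorded in result bundles,
which together with the master seed makes any run reproducible from
(input file, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # recording
    fs: float = 250.0
    scale: float = 1.0
    # labelling
    window_seconds: float = 1.0
    threshold: float | None = None          # manual global threshold (mV^2)
    derive_clean: str | None = None         # "start:end" seconds of artefact-free signal
    # segment extraction
    segment_seconds: float = 4.0
    prefix_seconds: float = 1.0
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    # model
    architecture: str = "lstm"
    input_len: int = 250
    output_len: int = 25
    # training
    learning_rate: float = 1e-4
    beta1: float = 0.9
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    validation_frequency: int = 1
    stride: int | None = None
    # evaluation / replacement
    horizon: int = 250
    armax_orders: str = "auto"
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a key-value document")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if isinstance(cfg.fractions, list):
            cfg.fractions = tuple(cfg.fractions)
        return cfg

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]
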