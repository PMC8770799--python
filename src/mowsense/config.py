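"""Experiment configuration: a validated tree loaded from YAML or JSON.

Sections mirror the pipeline stages (sim / preprocess / features /
model / train / eval / reject) plus a required global ``seed``.  Unknown
keys are rejected with the list of valid ones; missing keys fall back
to the documented defaults (EMA alpha 1/3, decision threshold 0.5,
215-day season, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig", "load_config"]


def _check_keys(section: str, data: dict, valid: list[str]) -> None:
    unknown = set(data) - set(valid)
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"valid keys: {sorted(valid)}"
        )


@dataclass
class _Section:
    @classmethod
    def from_dict(cls, name: str, data: dict):
        names = [f.name for f in _dc_fields(cls)]
        _check_keys(name, data, names)
        return cls(**data)


@dataclass
class SimSection(_Section):
    n_fields: int = 1000
    mown_fraction: float = 0.95
    max_events_per_field: int = 3
    ndvi_invalid_fraction: float = 0.75
    outlier_rate: float = 0.001
    s1_cadence_days: int = 6
    s2_cadence_days: int = 4
    noise_sd_ndvi: float = 0.02
    noise_sd_coh: float = 0.03
    rain_day_rate: float = 0.08


@dataclass
class PreprocessSection(_Section):
    smoothing_method: str = "ema"
    alpha: float = 1.0 / 3.0
    filter_width: int = 7
    outlier_threshold: float = 0.6
    outlier_max_span_days: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")


@dataclass
class FeaturesSection(_Section):
    label_width: int = 7


@dataclass
class ModelSection(_Section):
    conv_channels: tuple = (32, 32)
    kernel_size: int = 9
    hidden_activation: str = "softmax_channel"


@dataclass
class TrainSection(_Section):
    optimizer: str = "nadam"
    learning_rate: float = 1e-4
    max_epochs: int = 300
    batch_size: int = 64
    early_stopping_patience: int = 20


@dataclass
class EvalSection(_Section):
    threshold: float = 0.5
    min_run_days: int = 1
    season_score: str = "noisy_or"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")


@dataclass
class RejectSection(_Section):
    desired_tpr: float = 0.97
    desired_tnr: float = 0.75


@dataclass
class ExperimentConfig:
    seed: int
    n_days: int = 215
    sim: SimSection = field(default_factory=SimSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    eval: EvalSection = field(default_factory=EvalSection)
    reject: RejectSection = field(default_factory=RejectSection)


_SECTIONS = {
    "sim": SimSection, "preprocess": PreprocessSection, "features": FeaturesSection,
    "model": ModelSection, "train": TrainSection, "eval": EvalSection,
    "reject": RejectSection,
}


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    _check_keys("<root>", data, ["seed", "n_days", *_SECTIONS])
    if "seed" not in data:
        raise ValueError(f"{path}: required key 'seed' is missing")
    kwargs = {"seed": int(data["seed"])}
    if "n_days" in data:
        kwargs["n_days"] = int(data["n_days"])
    for name, cls in _SECTIONS.items():
        kwargs[name] = cls.from_dict(name, data.get(name, {}) or {})
    return ExperimentConfig(**kwargs)
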