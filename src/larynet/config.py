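"""Pipeline configuration: one YAML file drives every stage reproducibly.

Unknown keys are rejected; every defaulted value is explicit after load; the
canonical hash of the loaded config is embedded in each artifact the pipeline
writes so a run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import LRScheduleConfig, ModelConfig
from .synth import CLASSIFIER_KINDS


def _from_mapping(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SynthesisConfig:
    n_subjects: int = 18
    n_test_subjects: int = 2
    classes: tuple[str, ...] = CLASSIFIER_KINDS
    reps_per_class: int = 2
    fs: float = 333.0
    duration: float = 4.5
    jitter_lo: float = 0.0
    jitter_hi: float = 0.03

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)


@dataclass
class DSPConfig:
    hr_band: tuple[float, float] = (5.0, 25.0)
    rr_band: tuple[float, float] = (0.1, 0.7)

    def __post_init__(self) -> None:
        self.hr_band = tuple(self.hr_band)
        self.rr_band = tuple(self.rr_band)


@dataclass
class WindowingConfig:
    n_sequences: int = 100
    length: int = 1000


@dataclass
class TrainingConfig:
    epochs: int = 30
    iLR: float = 1e-2
    schedule_mode: str = "cosine_annealing"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    reduce_to_4: bool = False
    adapt_epochs: int = 20
    protocol: str = "within_subject"


@dataclass
class PipelineConfig:
    seed: int = 0
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    dsp: DSPConfig = field(default_factory=DSPConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    model: dict = field(default_factory=dict)  # overrides onto ModelConfig
    training: TrainingConfig = field(default_factory=TrainingConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs = {}
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        for name, sub in (
            ("synthesis", SynthesisConfig),
            ("dsp", DSPConfig),
            ("windowing", WindowingConfig),
            ("training", TrainingConfig),
        ):
            if name in data:
                kwargs[name] = _from_mapping(sub, data[name], name)
        if "model" in data:
            allowed_m = {f.name for f in fields(ModelConfig)}
            unknown_m = set(data["model"]) - allowed_m
            if unknown_m:
                raise ValueError(f"unknown key(s) in model: {sorted(unknown_m)}")
            kwargs["model"] = dict(data["model"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthesis"]["classes"] = list(d["synthesis"]["classes"])
        d["dsp"]["hr_band"] = list(d["dsp"]["hr_band"])
        d["dsp"]["rr_band"] = list(d["dsp"]["rr_band"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def model_config(self, n_classes: int) -> ModelConfig:
        overrides = dict(self.model)
        for key in ("block_convs", "channels_per_block"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        overrides.setdefault("epochs", self.training.epochs)
        return ModelConfig(n_classes=n_classes, **overrides)

    def schedule_config(self, epochs: int | None = None) -> LRScheduleConfig:
        return LRScheduleConfig(
            iLR=self.training.iLR,
            epochs=epochs or self.training.epochs,
            mode=self.training.schedule_mode,
        )
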