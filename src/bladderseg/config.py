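"""Pipeline configuration: one YAML document drives every stage.

Sections mirror the pipeline: ``phantom`` (generator), ``mask`` (hole
masking), ``network`` (trunk widths, latent size), ``loss`` (focal alphas,
gamma, Dice smoothing), ``pretrain`` / ``segment`` (stage training), ``lr``
(adaptive learning-rate policy) and ``inference`` (TTA/correction switches).
Every field has a default, so an empty document is a valid configuration,
and a config echoed back to disk reproduces the run.  Unknown keys are
rejected by name rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossWeights
from .networks import NetConfig
from .patching import MaskConfig
from .phantoms import PhantomConfig
from .training import LRPolicy, TrainConfig

__all__ = ["InferenceOptions", "PipelineConfig"]


@dataclass
class InferenceOptions:
    tta: bool = True
    correct: bool = True
    merge: str = "mean"            # "mean" | "vote"
    transforms: tuple = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270")
    connectivity: int = 8

    def __post_init__(self):
        if self.merge not in ("mean", "vote"):
            raise ValueError("merge must be 'mean' or 'vote'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _build(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {where!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys in {where!r}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        default = (f.default_factory() if f.default_factory is not dataclasses.MISSING
                   else f.default)
        if dataclasses.is_dataclass(default) and isinstance(v, dict):
            v = _build(type(default), v, f"{where}.{f.name}")
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


_SECTIONS = {
    "phantom": PhantomConfig,
    "mask": MaskConfig,
    "network": NetConfig,
    "loss": LossWeights,
    "pretrain": TrainConfig,
    "segment": TrainConfig,
    "lr": LRPolicy,
    "inference": InferenceOptions,
}


@dataclass
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    network: NetConfig = field(default_factory=NetConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    pretrain: TrainConfig = field(default_factory=lambda: TrainConfig(
        stage="pretrain", optimizer="adam", epochs=100, batch_size=16))
    segment: TrainConfig = field(default_factory=lambda: TrainConfig(
        stage="segment", optimizer="adamw", epochs=100, batch_size=16))
    lr: LRPolicy = field(default_factory=LRPolicy)
    inference: InferenceOptions = field(default_factory=InferenceOptions)
    seed: int = 0
    n_labeled: int = 42
    n_unlabeled: int = 54
    n_test: int = 10

    def __post_init__(self):
        # stage loss/mask settings follow the top-level sections
        self.pretrain.mask = self.mask
        self.segment.loss = self.loss

    @classmethod
    def from_dict(cls, data: dict | None) -> "PipelineConfig":
        data = dict(data or {})
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            if name in data:
                kwargs[name] = _build(section_cls, data[name] or {}, name)
        for name in ("seed", "n_labeled", "n_unlabeled", "n_test"):
            if name in data:
                kwargs[name] = int(data[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
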