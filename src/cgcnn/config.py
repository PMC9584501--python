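"""Run configuration: nested parameter dataclasses, YAML round-trip, seeding.

A single top-level seed fans out to named substreams (one per pipeline
stage), so e.g. changing the augmentation scheme does not perturb weight
initialization.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, asdict

import numpy as np
import yaml

from .representations import RepresentationParams

__all__ = ["AugmentParams", "TrainParams", "ModelParams", "RunConfig",
           "substream_seed", "load_config", "dump_config"]


def substream_seed(seed: int, name: str) -> int:
    """Derive a deterministic per-stage seed from the top-level seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1)[0])


@dataclass
class AugmentParams:
    """Training-fold augmentation. scheme: none | sliding_window | white_noise."""

    scheme: str = "none"
    window_s: float = 2.0
    step_s: float = 0.32
    snr_db: float = 20.0
    copies: int = 3

    def __post_init__(self):
        if self.scheme not in ("none", "sliding_window", "white_noise"):
            raise ValueError(f"unknown augmentation scheme {self.scheme!r}")


@dataclass
class TrainParams:
    lr: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    early_stopping: bool = False
    patience: int = 10
    val_fraction: float = 0.1


@dataclass
class ModelParams:
    """Architecture knobs that do not depend on the data shape."""

    cheb_order: int = 3
    c1: int = 64
    c2: int = 64
    kernel_t: int = 5
    use_st_branch: bool = True
    use_ss_branch: bool = True
    use_attention: bool = True
    use_global_aggregation: bool = True
    use_shortcut: bool = True
    attention_norm: str = "row"


@dataclass
class RunConfig:
    montage_csv: str = None
    trials_h5: str = None
    output_dir: str = "."
    representation: RepresentationParams = field(default_factory=RepresentationParams)
    augment: AugmentParams = field(default_factory=AugmentParams)
    model: ModelParams = field(default_factory=ModelParams)
    train: TrainParams = field(default_factory=TrainParams)
    n_folds: int = 5
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _build(cls, d, "config")


_NESTED = {
    "representation": RepresentationParams,
    "augment": AugmentParams,
    "model": ModelParams,
    "train": TrainParams,
}


def _build(cls, d: dict, where: str):
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ValueError(f"{where}: expected a mapping, got {type(d).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in d.items():
        sub = _NESTED.get(key)
        if sub is not None and cls is RunConfig:
            kwargs[key] = _build(sub, value, f"{where}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def dump_config(config: RunConfig, path) -> None:
    d = config.to_dict()
    d["representation"]["band"] = list(d["representation"]["band"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
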