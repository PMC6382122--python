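"""Run configuration: training hyperparameters and pipeline settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Hyperparameters for the temporal-orientation network and pipeline.

    Defaults follow the published training protocol: categorical
    cross-entropy loss, RMSprop, batch size 128, dropout 0.2, a 10%
    validation split, and convolution windows of 5/6/7 tokens over the
    linguistic-feature matrix.  ``epochs`` defaults to 100 as published;
    desk-scale runs typically override it downward.
    """

    loss_name: str = "categorical_cross_entropy"
    optimizer_name: str = "rmsprop"
    epochs: int = 100
    batch_size: int = 128
    dropout_rate: float = 0.2
    max_seq_len: int = 50
    cnn_windows: tuple[int, ...] = (5, 6, 7)
    cnn_filters_per_window: int = 32
    validation_fraction: float = 0.10
    seed: int = 42
    # architecture knobs the publication leaves open
    hidden_size: int = 64
    attention_size: int | None = None  # None -> 2 * hidden_size
    learning_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.loss_name != "categorical_cross_entropy":
            raise ValueError(f"unsupported loss: {self.loss_name!r}")
        if self.optimizer_name not in ("rmsprop", "adam", "sgd"):
            raise ValueError(f"unsupported optimizer: {self.optimizer_name!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1 or self.max_seq_len < 1:
            raise ValueError("epochs/batch_size/max_seq_len out of range")
        self.cnn_windows = tuple(int(w) for w in self.cnn_windows)
        if not self.cnn_windows or any(w < 1 for w in self.cnn_windows):
            raise ValueError("cnn_windows must be positive integers")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cnn_windows"] = list(self.cnn_windows)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
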