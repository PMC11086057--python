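"""Structured (YAML) run configuration with fail-fast unknown-key checking."""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .losses import LossConfig
from .model import ModelConfig
from .pipeline import TrainConfig

__all__ = ["RunConfig", "load_run_config"]


def _build(cls, payload: dict[str, Any], section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}' config section: {sorted(unknown)}")
    if cls is ModelConfig and "decoder_channels" in payload:
        payload = {**payload, "decoder_channels": tuple(payload["decoder_channels"])}
    return cls(**payload)


@dataclasses.dataclass
class RunConfig:
    """Merged model + training + loss configuration plus run paths."""

    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    data_dir: str | None = None
    out_dir: str | None = None
    checkpoint: str | None = None
    log_level: str = "INFO"


def load_run_config(path: str | None = None, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load a YAML config; sections: model, train, loss (nested under train),
    and flat path keys.  Unknown keys anywhere are errors."""
    payload: dict[str, Any] = {}
    if path:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    if overrides:
        for key, val in overrides.items():
            if val is None:
                continue
            sect, _, name = key.partition(".")
            if name:
                payload.setdefault(sect, {})[name] = val
            else:
                payload[key] = val
    known_top = {"model", "train", "loss", "data_dir", "out_dir", "checkpoint", "log_level"}
    unknown = set(payload) - known_top
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    loss = _build(LossConfig, payload.get("loss", {}), "loss")
    train_payload = dict(payload.get("train", {}))
    if "loss" in train_payload:
        raise ValueError("place loss settings in the top-level 'loss' section")
    train = _build(TrainConfig, train_payload, "train")
    train = dataclasses.replace(train, loss=loss)
    model = _build(ModelConfig, payload.get("model", {}), "model")
    return RunConfig(
        model=model,
        train=train,
        data_dir=payload.get("data_dir"),
        out_dir=payload.get("out_dir"),
        checkpoint=payload.get("checkpoint"),
        log_level=payload.get("log_level", "INFO"),
    )
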