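"""YAML run configuration.

One file drives the whole pipeline, with sections mirroring the modules:

    seed: 0
    phantom:        {height, width, n_layers, n_vessels, ...}
    simulation:     {noise: {model, sigma, correlation, jitter_px}, n_frames, split}
    augmentation:   {a_range, ..., p_apply, noise: {...}}
    network:        {family, levels, base_channels, upsampling}
    training:       {epochs, learning_rate, batch_size}
    ensemble:       {use_histeq}

Every section is validated against its module's invariants before any
work starts; errors name the offending key path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .augment import AugmentationConfig
from .errors import ConfigError
from .networks import NetworkSpec
from .phantom import DatasetConfig, NoiseSpec, PhantomConfig
from .training import TrainConfig


def _build(cls, raw: dict[str, Any], path: str):
    """Construct a config dataclass from a mapping, naming bad keys."""
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(raw).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key == "noise" and isinstance(value, dict):
            value = _build(NoiseSpec, value, f"{path}.noise")
        elif key == "augmentation" and isinstance(value, dict):
            value = _build(AugmentationConfig, value, f"{path}.augmentation")
        elif key == "phantom" and isinstance(value, dict):
            value = _build(PhantomConfig, value, f"{path}.phantom")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ConfigError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunConfig:
    """Validated configuration for every pipeline stage."""

    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    simulation: DatasetConfig = field(default_factory=DatasetConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    use_histeq: bool = True

    def digest(self) -> str:
        """Short stable hash of the configuration, for logging."""

        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | None) -> RunConfig:
    """Load and validate a YAML config; None yields defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {"seed", "phantom", "simulation", "augmentation", "network", "training", "ensemble"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    cfg = RunConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "phantom" in raw:
        cfg.phantom = _build(PhantomConfig, raw["phantom"], "phantom")
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        sim.setdefault("phantom", {})
        if isinstance(sim["phantom"], dict) and "phantom" in raw:
            sim["phantom"] = {**raw["phantom"], **sim["phantom"]}
        cfg.simulation = _build(DatasetConfig, sim, "simulation")
    else:
        cfg.simulation = DatasetConfig(phantom=cfg.phantom)
    if "augmentation" in raw:
        cfg.augmentation = _build(AugmentationConfig, raw["augmentation"], "augmentation")
    if "network" in raw:
        cfg.network = _build(NetworkSpec, raw["network"], "network")
    if "training" in raw:
        cfg.training = _build(TrainConfig, raw["training"], "training")
    if "ensemble" in raw:
        ens = raw["ensemble"]
        if not isinstance(ens, dict) or set(ens) - {"use_histeq"}:
            raise ConfigError("ensemble: only key 'use_histeq' is supported")
        cfg.use_histeq = bool(ens.get("use_histeq", True))
    return cfg
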