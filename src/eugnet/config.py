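"""YAML run configuration: one block per component, strict key checking.

A run file looks like

    seed: 7
    scene:    {height: 64, width: 64, n_tools: 2}
    augment:  {hflip_prob: 0.5, rotation_range: [-15, 15]}
    gridmask: {r: 0.6, d_range: [8, 24], apply_prob: 0.5}
    model:    {variant: eugnet, depth: 4, base_channels: 8}
    train:    {epochs: 10, batch_size: 8}

Absent keys take the component defaults; unknown keys raise a
ConfigError naming the offending key path (catching typos early).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .gridmask import GridMaskPolicy
from .model import ModelConfig
from .synthdata import SceneConfig
from .train_eval import TrainConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Configuration parse or validation failure, with the key path."""


def _build(cls, data: dict | None, path: str):
    """Instantiate dataclass `cls` from a mapping, rejecting unknown keys
    and converting YAML lists to tuples where the field default is one."""
    data = dict(data or {})
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) under '{path}': {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        default = fields[k].default
        if isinstance(v, list) and (isinstance(default, tuple) or
                                    "tuple" in str(fields[k].type)):
            v = tuple(v)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{path}' block: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Composite of every component's configuration plus run-level paths."""

    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    gridmask: GridMaskPolicy = field(default_factory=GridMaskPolicy)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_scenes: int = 200
    data_dir: str | None = None

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one root seed to every randomized component."""
        return dataclasses.replace(
            self,
            seed=seed,
            scene=dataclasses.replace(self.scene, seed=seed),
            train=dataclasses.replace(self.train, seed=seed),
        )


_TOP_KEYS = {"seed", "scene", "augment", "gridmask", "model", "train",
             "n_scenes", "data_dir"}


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    An empty file yields the all-defaults RunConfig.  Unknown keys at any
    level raise :class:`ConfigError` with the key path.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    gm = _build(GridMaskPolicy, raw.get("gridmask"), "gridmask")
    aug = _build(AugmentConfig, raw.get("augment"), "augment")
    train_block = dict(raw.get("train") or {})
    for nested in ("gridmask", "augment"):
        if nested in train_block:
            raise ConfigError(
                f"'train.{nested}' is configured via the top-level '{nested}' block"
            )
    tr = _build(TrainConfig, train_block, "train")
    tr = dataclasses.replace(tr, gridmask=gm, augment=aug)

    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        scene=_build(SceneConfig, raw.get("scene"), "scene"),
        augment=aug,
        gridmask=gm,
        model=_build(ModelConfig, raw.get("model"), "model"),
        train=tr,
        n_scenes=int(raw.get("n_scenes", 200)),
        data_dir=raw.get("data_dir"),
    )
    if cfg.n_scenes < 1:
        raise ConfigError("n_scenes must be >= 1")
    if cfg.data_dir is not None and not Path(cfg.data_dir).exists():
        raise ConfigError(f"data_dir does not exist: {cfg.data_dir}")
    return cfg


def _clean(dc) -> dict:
    out = {}
    for f in dataclasses.fields(dc):
        v = getattr(dc, f.name)
        if isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig to canonical YAML; load(dump(x)) == x."""
    train = _clean(cfg.train)
    train.pop("gridmask")
    train.pop("augment")
    doc = {
        "seed": cfg.seed,
        "scene": _clean(cfg.scene),
        "augment": _clean(cfg.augment),
        "gridmask": _clean(cfg.gridmask),
        "model": _clean(cfg.model),
        "train": train,
        "n_scenes": cfg.n_scenes,
        "data_dir": cfg.data_dir,
    }
    return yaml.safe_dump(doc, sort_keys=True)
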