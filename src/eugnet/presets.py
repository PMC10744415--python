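"""Canonical desk-scale study conditions.

One place defines the synthetic-scene statistics, augmentation ranges,
GridMask policy and training schedule used by the end-to-end experiments
(library examples, CLI defaults documentation, and the acceptance script),
so every consumer runs the same conditions.

The GridMask unit range (8, 24) px is the 576-px-frame convention
(24, 64) scaled proportionally to 64-px scenes; the keep-ratio stays 0.6.
"""

from __future__ import annotations

from .augment import AugmentConfig
from .gridmask import GridMaskPolicy
from .model import ModelConfig
from .synthdata import SceneConfig
from .train_eval import TrainConfig

__all__ = ["study_augment", "study_gridmask", "study_scene", "study_model",
           "study_train"]


def study_augment() -> AugmentConfig:
    """Modest standard augmentation: ±15 deg rotation, flips, small
    brightness shift and sensor-like noise."""
    return AugmentConfig(
        rotation_range=(-15.0, 15.0),
        hflip_prob=0.5,
        vflip_prob=0.25,
        brightness_range=(-0.1, 0.1),
        noise_std=0.02,
    )


def study_gridmask(apply_prob: float = 0.5) -> GridMaskPolicy:
    return GridMaskPolicy(d_range=(8, 24), r=0.6, apply_prob=apply_prob,
                          rotate=True, mask_labels=False)


def study_scene(seed: int = 0, size: int = 64) -> SceneConfig:
    return SceneConfig(height=size, width=size, n_tools=2, seed=seed)


def study_model(depth: int = 4, base_channels: int = 8) -> ModelConfig:
    return ModelConfig(variant="eugnet", depth=depth, base_channels=base_channels)


def study_train(seed: int = 0, epochs: int = 10,
                apply_prob: float = 0.5) -> TrainConfig:
    return TrainConfig(
        epochs=epochs,
        batch_size=8,
        seed=seed,
        gridmask=study_gridmask(apply_prob),
        augment=study_augment(),
    )
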