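"""Synthetic surgical-tool scenes with pixel-exact ground truth.

The generator emulates the statistical structure of endoscopic instrument
footage without requiring any video data: a smoothly varying reddish
tissue-like background (correlated noise), one or more elongated metallic
tools entering from the image borders (biased towards the bottom corners,
the way laparoscopic instruments appear) with an articulated tip and an
optional specular streak, plus optional tissue-coloured occluders and red
splash-like blobs.  Foreground (tool) pixels are a small fraction of the
image, reproducing the class imbalance that motivates a class-balanced
loss.  Everything is deterministic under the configured seed, including
the bytes of files written to disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["SceneConfig", "SegDataset", "generate_scene", "generate_dataset",
           "load_dataset", "occluded_variant"]


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry and appearance parameters (pixels unless noted)."""

    height: int = 64
    width: int = 64
    n_tools: int = 2
    tool_width_range: tuple[int, int] = (4, 8)
    tool_length_range: tuple[int, int] = (40, 70)
    background_scale: float = 8.0       # correlation length of tissue texture
    background_contrast: float = 0.5    # 0..1 amplitude of the texture
    specular_prob: float = 0.7
    occluder_prob: float = 0.3
    occluder_size_range: tuple[int, int] = (4, 10)
    splash_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError("height and width must be >= 8")
        if self.n_tools < 0:
            raise ValueError("n_tools must be >= 0")
        for name in ("tool_width_range", "tool_length_range", "occluder_size_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi")
        if self.tool_width_range[1] >= min(self.height, self.width):
            raise ValueError("tool width exceeds image size")
        for name in ("specular_prob", "occluder_prob", "splash_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.background_contrast <= 1.0):
            raise ValueError("background_contrast must be in [0, 1]")


@dataclass
class SegDataset:
    """In-memory paired dataset: images (N,H,W,3) float32 in [0,1] and
    binary masks (N,H,W) uint8."""

    images: np.ndarray
    masks: np.ndarray

    def __post_init__(self):
        if self.images.ndim != 4 or self.masks.ndim != 3:
            raise ValueError("images must be (N,H,W,3), masks (N,H,W)")
        if self.images.shape[:3] != self.masks.shape:
            raise ValueError("images and masks are misaligned")

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, idx) -> "SegDataset":
        return SegDataset(self.images[idx].copy(), self.masks[idx].copy())


def _capsule(h: int, w: int, p0, p1, radius: float) -> np.ndarray:
    """Boolean mask of points within `radius` of segment p0-p1."""
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    p0 = np.asarray(p0, dtype=np.float64)
    d = np.asarray(p1, dtype=np.float64) - p0
    l2 = float(d @ d)
    if l2 == 0.0:
        dist2 = (yy - p0[0]) ** 2 + (xx - p0[1]) ** 2
    else:
        t = np.clip(((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / l2, 0.0, 1.0)
        dist2 = (yy - (p0[0] + t * d[0])) ** 2 + (xx - (p0[1] + t * d[1])) ** 2
    return dist2 <= radius * radius


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    tex = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.background_scale / 2)
    tex = (tex - tex.min()) / (np.ptp(tex) + 1e-9) - 0.5
    fine = 0.03 * rng.standard_normal((h, w))
    base = np.empty((h, w, 3), dtype=np.float32)
    base[..., 0] = 0.55 + cfg.background_contrast * 0.35 * tex + fine   # red
    base[..., 1] = 0.28 + cfg.background_contrast * 0.18 * tex + fine   # green
    base[..., 2] = 0.26 + cfg.background_contrast * 0.15 * tex + fine   # blue
    return base


def _one_tool(cfg: SceneConfig, rng: np.random.Generator):
    """Shaft + articulated tip capsules; returns (mask, entry->tip geometry)."""
    h, w = cfg.height, cfg.width
    # entry point on a border, biased to the bottom corners
    corner_bias = rng.random() < 0.6
    if corner_bias:
        y0 = h - 1 + rng.uniform(0, 3)
        x0 = rng.uniform(0, 0.25 * w) if rng.random() < 0.5 else rng.uniform(0.75 * w, w - 1)
    else:
        side = rng.integers(0, 4)
        if side == 0:
            y0, x0 = 0.0 - rng.uniform(0, 3), rng.uniform(0, w - 1)
        elif side == 1:
            y0, x0 = h - 1 + rng.uniform(0, 3), rng.uniform(0, w - 1)
        elif side == 2:
            y0, x0 = rng.uniform(0, h - 1), 0.0 - rng.uniform(0, 3)
        else:
            y0, x0 = rng.uniform(0, h - 1), w - 1 + rng.uniform(0, 3)
    target = np.array([h / 2, w / 2]) + rng.uniform(-0.15, 0.15, 2) * np.array([h, w])
    direction = target - np.array([y0, x0])
    direction /= np.linalg.norm(direction) + 1e-9
    length = rng.uniform(*cfg.tool_length_range)
    width = rng.uniform(*cfg.tool_width_range)
    p0 = np.array([y0, x0])
    p1 = p0 + direction * length
    shaft = _capsule(h, w, p0, p1, width / 2)
    # articulated tip: short capsule at an angle off the shaft axis
    ang = rng.uniform(-0.7, 0.7)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    tip_dir = rot @ direction
    p2 = p1 + tip_dir * (0.25 * length)
    tip = _capsule(h, w, p1, p2, width / 2 * 1.15)
    return shaft | tip, (p0, p2, width)


def _shade_tool(img, tool_mask, geom, cfg, rng):
    p0, p2, width = geom
    gray = rng.uniform(0.55, 0.85)
    tint = rng.uniform(-0.03, 0.03)
    color = np.array([gray - tint, gray, gray + tint], dtype=np.float32)
    noise = 0.04 * rng.standard_normal(tool_mask.shape).astype(np.float32)
    for c in range(3):
        img[..., c][tool_mask] = color[c] + noise[tool_mask]
    if rng.random() < cfg.specular_prob:
        streak = _capsule(*tool_mask.shape, p0, p2, max(width / 6.0, 0.7)) & tool_mask
        for c in range(3):
            img[..., c][streak] += 0.18
    return img


def _blob(h, w, center, radius, rng) -> np.ndarray:
    """Irregular blob: smoothed noise thresholded inside a disk."""
    disk = _capsule(h, w, center, center, radius)
    if not disk.any():
        return disk
    rough = ndimage.gaussian_filter(rng.standard_normal((h, w)), radius / 2.5)
    return disk & (rough > np.quantile(rough[disk], 0.25))


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene.  Returns (image (H,W,3) float32 in [0,1],
    label (H,W) uint8 in {0,1}).  Deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    img = _background(config, rng)
    label = np.zeros((h, w), dtype=np.uint8)
    for _ in range(config.n_tools):
        tool, geom = _one_tool(config, rng)
        img = _shade_tool(img, tool, geom, config, rng)
        label[tool] = 1
    if config.n_tools and rng.random() < config.occluder_prob:
        # tissue-coloured blob overlapping a tool; the label keeps the tool
        ys, xs = np.nonzero(label)
        if len(ys):
            i = rng.integers(0, len(ys))
            radius = rng.uniform(*config.occluder_size_range)
            blob = _blob(h, w, (ys[i], xs[i]), radius, rng)
            img[blob] = [0.62, 0.33, 0.30] + 0.05 * rng.standard_normal(3)
    if rng.random() < config.splash_prob:
        center = rng.uniform([0, 0], [h - 1, w - 1])
        blob = _blob(h, w, center, rng.uniform(3, max(4, h / 8)), rng)
        img[blob] = [0.75, 0.08, 0.08] + 0.05 * rng.standard_normal(3)
    return np.clip(img, 0.0, 1.0).astype(np.float32), label


def _scene_batch(config: SceneConfig, n_scenes: int) -> SegDataset:
    images, masks = [], []
    for i in range(n_scenes):
        img, lab = generate_scene(replace(config, seed=config.seed + i))
        images.append(img)
        masks.append(lab)
    return SegDataset(np.stack(images), np.stack(masks))


def generate_dataset(config: SceneConfig, n_scenes: int, out_dir=None):
    """Generate n_scenes scenes; if out_dir is given, write images/NNN.png,
    masks/NNN.png and manifest.json and return the manifest dict, otherwise
    return the in-memory :class:`SegDataset`."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    ds = _scene_batch(config, n_scenes)
    if out_dir is None:
        return ds
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_scenes):
        img8 = np.round(ds.images[i] * 255.0).astype(np.uint8)
        msk8 = (ds.masks[i] * 255).astype(np.uint8)
        ip, mp = f"images/{i:03d}.png", f"masks/{i:03d}.png"
        Image.fromarray(img8).save(out / ip)
        Image.fromarray(msk8).save(out / mp)
        entries.append({
            "image": ip, "mask": mp,
            "sha256": hashlib.sha256(img8.tobytes() + msk8.tobytes()).hexdigest(),
        })
    manifest = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in config.__dict__.items()},
        "n_scenes": n_scenes,
        "entries": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_dataset(in_dir) -> SegDataset:
    """Read a dataset written by :func:`generate_dataset`."""
    root = Path(in_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    images, masks = [], []
    for e in manifest["entries"]:
        img = np.asarray(Image.open(root / e["image"]), dtype=np.float32) / 255.0
        msk = (np.asarray(Image.open(root / e["mask"])) > 127).astype(np.uint8)
        images.append(img)
        masks.append(msk)
    return SegDataset(np.stack(images), np.stack(masks))


def occluded_variant(dataset: SegDataset, occlusion_level: float,
                     rng: np.random.Generator) -> SegDataset:
    """Add tissue-coloured occluders covering about `occlusion_level` of
    each scene's tool pixels.  Labels are returned unchanged, so a robust
    model must still predict the full tool extent."""
    if not (0.0 <= occlusion_level <= 1.0):
        raise ValueError(f"occlusion_level must be in [0, 1], got {occlusion_level}")
    images = dataset.images.copy()
    masks = dataset.masks.copy()
    if occlusion_level == 0.0:
        return SegDataset(images, masks)
    h, w = masks.shape[1:]
    radius = max(2.0, min(h, w) / 20.0)
    for n in range(len(dataset)):
        ys, xs = np.nonzero(masks[n])
        total = len(ys)
        if total == 0:
            continue
        covered = np.zeros((h, w), dtype=bool)
        target = occlusion_level * total
        for _ in range(200):
            missing = target - (covered & (masks[n] > 0)).sum()
            if missing <= 0:
                break
            i = rng.integers(0, total)
            disk = _capsule(h, w, (ys[i], xs[i]), (ys[i], xs[i]), radius)
            covered |= disk
            color = np.array([0.60, 0.32, 0.29]) + 0.04 * rng.standard_normal(3)
            images[n][disk] = np.clip(color, 0, 1).astype(np.float32)
    return SegDataset(images, masks)
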