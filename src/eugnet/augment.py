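"""Standard paired image/label augmentation applied before GridMask.

Geometric transforms (rotation, flips, scaling, translation, elastic
deformation, cropping) use identical parameters for the image and its label
mask; the label is resampled with nearest-neighbour interpolation so it
stays strictly binary.  Photometric transforms (brightness shift, additive
Gaussian noise) touch the image only, so the label's foreground pixel count
can change only through resampling or cropping.  Out-of-bounds regions are
filled with 0 (black image, background label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "apply_standard"]


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges for each transform; a degenerate/zero range disables it.

    rotation_range : degrees, inclusive interval to draw the angle from.
    hflip_prob / vflip_prob : flip probabilities.
    scale_range : multiplicative zoom interval (1.0 = identity).
    translate_range : pixel shift interval, drawn per axis.
    elastic_alpha : displacement amplitude in pixels (0 disables).
    elastic_sigma : Gaussian smoothing scale of the displacement field.
    brightness_range : additive intensity shift interval.
    noise_std : standard deviation of additive Gaussian noise.
    crop_size : (h, w) of a random crop, or None.
    """

    rotation_range: tuple[float, float] = (0.0, 0.0)
    hflip_prob: float = 0.0
    vflip_prob: float = 0.0
    scale_range: tuple[float, float] = (1.0, 1.0)
    translate_range: tuple[float, float] = (0.0, 0.0)
    elastic_alpha: float = 0.0
    elastic_sigma: float = 8.0
    brightness_range: tuple[float, float] = (0.0, 0.0)
    noise_std: float = 0.0
    crop_size: tuple[int, int] | None = None

    def __post_init__(self):
        for name in ("hflip_prob", "vflip_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("rotation_range", "scale_range", "translate_range",
                     "brightness_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} must be (lo, hi) with lo <= hi")
        if self.noise_std < 0 or self.elastic_alpha < 0 or self.elastic_sigma <= 0:
            raise ValueError("noise_std/elastic_alpha must be >= 0, elastic_sigma > 0")


def _affine_active(angle: float, scale: float, shift: tuple[float, float]) -> bool:
    return angle != 0.0 or scale != 1.0 or shift != (0.0, 0.0)


def apply_standard(image: np.ndarray, label: np.ndarray, config: AugmentConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply the configured transforms jointly to (image, label).

    Returns new arrays; with everything disabled the inputs are returned
    bit-identical.  Output intensities are clipped to [0, 1].
    """
    image = np.asarray(image, dtype=np.float32)
    label = np.asarray(label)
    if label.shape != image.shape[:2]:
        raise ValueError(
            f"label shape {label.shape} does not match image spatial shape {image.shape[:2]}"
        )

    # geometric: one combined affine (rotation + isotropic scale + shift)
    angle = float(rng.uniform(*config.rotation_range)) \
        if config.rotation_range != (0.0, 0.0) else 0.0
    scale = float(rng.uniform(*config.scale_range)) \
        if config.scale_range != (1.0, 1.0) else 1.0
    shift = (0.0, 0.0)
    if config.translate_range != (0.0, 0.0):
        shift = (float(rng.uniform(*config.translate_range)),
                 float(rng.uniform(*config.translate_range)))

    if _affine_active(angle, scale, shift):
        image, label = _affine_pair(image, label, angle, scale, shift)

    if config.hflip_prob and rng.random() < config.hflip_prob:
        image, label = image[:, ::-1].copy(), label[:, ::-1].copy()
    if config.vflip_prob and rng.random() < config.vflip_prob:
        image, label = image[::-1].copy(), label[::-1].copy()

    if config.elastic_alpha > 0:
        image, label = _elastic_pair(image, label, config.elastic_alpha,
                                     config.elastic_sigma, rng)

    if config.crop_size is not None:
        ch, cw = config.crop_size
        h, w = label.shape
        if ch > h or cw > w:
            raise ValueError(f"crop_size {config.crop_size} exceeds image size {(h, w)}")
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        image = image[top:top + ch, left:left + cw].copy()
        label = label[top:top + ch, left:left + cw].copy()

    # photometric: image only
    if config.brightness_range != (0.0, 0.0):
        image = image + float(rng.uniform(*config.brightness_range))
    if config.noise_std > 0:
        image = image + rng.normal(0.0, config.noise_std, image.shape).astype(np.float32)
    if config.brightness_range != (0.0, 0.0) or config.noise_std > 0:
        image = np.clip(image, 0.0, 1.0)

    return image, label


def _affine_pair(image, label, angle_deg, scale, shift):
    h, w = label.shape
    theta = np.deg2rad(angle_deg)
    # output->input map: rotate by -theta and divide by scale, about center
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]]) / scale
    rot[np.abs(rot) < 1e-12] = 0.0  # right-angle rotations map grid to grid
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = np.round(center - rot @ (center + np.array(shift)), 12)
    if image.ndim == 3:
        out_img = np.stack([
            ndimage.affine_transform(image[..., c], rot, offset=offset,
                                     order=1, mode="constant", cval=0.0)
            for c in range(image.shape[2])
        ], axis=-1).astype(np.float32)
    else:
        out_img = ndimage.affine_transform(image, rot, offset=offset, order=1,
                                           mode="constant", cval=0.0).astype(np.float32)
    out_lab = ndimage.affine_transform(label, rot, offset=offset, order=0,
                                       mode="constant", cval=0).astype(label.dtype)
    return out_img, out_lab


def _elastic_pair(image, label, alpha, sigma, rng):
    h, w = label.shape
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.array([yy + dy, xx + dx])
    if image.ndim == 3:
        out_img = np.stack([
            ndimage.map_coordinates(image[..., c], coords, order=1,
                                    mode="constant", cval=0.0)
            for c in range(image.shape[2])
        ], axis=-1).astype(np.float32)
    else:
        out_img = ndimage.map_coordinates(image, coords, order=1, mode="constant",
                                          cval=0.0).astype(np.float32)
    out_lab = ndimage.map_coordinates(label, coords, order=0, mode="constant",
                                      cval=0).astype(label.dtype)
    return out_img, out_lab
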