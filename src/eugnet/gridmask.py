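"""GridMask structured-erasure augmentation.

GridMask removes a periodic lattice of square regions from an input image:
the plane is tiled with d x d units, each unit loses a square of side
s = round((1 - r) * d) at its origin, and the whole pattern is translated
by (delta_y, delta_x) and optionally rotated.  The augmented image is the
element-wise product X_tilde = X * M of the image with the binary mask M.
Unlike Cutout-style erasure the dropped regions are disconnected and
uniformly distributed, which preserves global context while simulating the
partial occlusions (tissue, blood, other instruments) that surgical tools
suffer in endoscopic video.

The keep-ratio r in (0, 1] controls how much of each unit survives
(asymptotic kept fraction 1 - (1-r)^2); d sets the spatial scale of the
erasure; delta_x / delta_y shift the lattice so the network never sees the
holes in the same place twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["GridSpec", "GridMaskPolicy", "generate_mask", "apply_mask",
           "sample_spec", "augment_sample"]


@dataclass(frozen=True)
class GridSpec:
    """The four GridMask parameters plus an optional lattice rotation.

    r : keep-ratio in (0, 1] — ratio of the kept ("gray") edge of a unit.
    d : side length of one unit in pixels (>= 1).
    delta_x, delta_y : lattice offsets in pixels, each in [0, d).
    rotation_deg : rotation of the whole lattice, degrees.
    """

    r: float
    d: int
    delta_x: int = 0
    delta_y: int = 0
    rotation_deg: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.r <= 1.0):
            raise ValueError(f"keep-ratio r must be in (0, 1], got {self.r}")
        if self.d < 1:
            raise ValueError(f"unit length d must be >= 1, got {self.d}")
        for name in ("delta_x", "delta_y"):
            v = getattr(self, name)
            if not (0 <= v < self.d):
                raise ValueError(f"{name} must be in [0, d={self.d}), got {v}")

    @property
    def drop_side(self) -> int:
        """Side of the dropped square within each unit."""
        return int(round((1.0 - self.r) * self.d))


@dataclass(frozen=True)
class GridMaskPolicy:
    """How GridMask is sampled and applied during training.

    d_range : inclusive interval the unit length d is drawn from.
    r : fixed keep-ratio.
    apply_prob : probability of applying GridMask to a given sample.
    rotate : draw a random lattice rotation in [0, 360).
    mask_labels : also multiply the label mask by M.  Off by default —
        the ground truth keeps the full tool extent so the network learns
        to predict tool pixels *through* the erased regions rather than
        to reproduce the holes.
    """

    d_range: tuple[int, int] = (24, 64)
    r: float = 0.6
    apply_prob: float = 0.5
    rotate: bool = True
    mask_labels: bool = False

    def __post_init__(self):
        lo, hi = self.d_range
        if lo < 2 or hi < lo:
            raise ValueError(f"d_range must satisfy 2 <= lo <= hi, got {self.d_range}")
        if not (0.0 <= self.apply_prob <= 1.0):
            raise ValueError(f"apply_prob must be in [0, 1], got {self.apply_prob}")
        if not (0.0 < self.r <= 1.0):
            raise ValueError(f"r must be in (0, 1], got {self.r}")


def generate_mask(spec: GridSpec, height: int, width: int) -> np.ndarray:
    """Construct the binary GridMask M of shape (height, width).

    Entries are 1 (keep) except on the dropped lattice: M[i, j] = 0 iff
    ((i - delta_y) mod d) < s and ((j - delta_x) mod d) < s with
    s = round((1 - r) * d).  A nonzero rotation is realized by building the
    mask on an enlarged square canvas, rotating with nearest-neighbour
    interpolation (so values stay exactly {0, 1}) and center-cropping,
    which avoids unmasked corner artifacts.
    """
    if height < 1 or width < 1:
        raise ValueError(f"height and width must be >= 1, got {height}x{width}")
    if spec.rotation_deg % 360.0 == 0.0:
        return _lattice(spec, height, width)
    side = int(np.ceil(np.sqrt(2.0) * max(height, width)))
    big = _lattice(spec, side, side)
    rot = ndimage.rotate(big, spec.rotation_deg, reshape=False, order=0,
                         mode="constant", cval=1)
    top = (side - height) // 2
    left = (side - width) // 2
    return np.ascontiguousarray(rot[top:top + height, left:left + width])


def _lattice(spec: GridSpec, height: int, width: int) -> np.ndarray:
    s = spec.drop_side
    ii = (np.arange(height) - spec.delta_y) % spec.d
    jj = (np.arange(width) - spec.delta_x) % spec.d
    dropped = (ii[:, None] < s) & (jj[None, :] < s)
    return (~dropped).astype(np.uint8)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """X_tilde = X * M, applied to every channel; the input is not modified."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image spatial shape {image.shape[:2]}"
        )
    m = mask if image.ndim == 2 else mask[..., None]
    return image * m.astype(image.dtype)


def sample_spec(policy: GridMaskPolicy, rng: np.random.Generator) -> GridSpec:
    """Draw one GridSpec: d uniform over d_range, offsets uniform in [0, d),
    rotation uniform in [0, 360) when enabled.  Deterministic under seed."""
    lo, hi = policy.d_range
    d = int(rng.integers(lo, hi + 1))
    dx = int(rng.integers(0, d))
    dy = int(rng.integers(0, d))
    rot = float(rng.uniform(0.0, 360.0)) if policy.rotate else 0.0
    return GridSpec(r=policy.r, d=d, delta_x=dx, delta_y=dy, rotation_deg=rot)


def augment_sample(image: np.ndarray, label: np.ndarray, policy: GridMaskPolicy,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply GridMask to (image, label) with probability `apply_prob`.

    The label is multiplied by M only when `mask_labels` is set; otherwise
    it is returned unchanged.
    """
    if label.shape != image.shape[:2]:
        raise ValueError(
            f"label shape {label.shape} does not match image spatial shape {image.shape[:2]}"
        )
    if rng.random() >= policy.apply_prob:
        return image, label
    spec = sample_spec(policy, rng)
    mask = generate_mask(spec, image.shape[0], image.shape[1])
    out_img = apply_mask(image, mask)
    out_lab = apply_mask(label, mask) if policy.mask_labels else label
    return out_img, out_lab
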