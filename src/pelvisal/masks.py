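"""Point annotations -> multi-resolution binary supervision masks.

A point annotation is expanded into a disk of radius ``s`` (default 75 px at
the 1024 px working resolution): mask pixel (i, j) is 1 iff the Euclidean
distance from its center to any annotation point is <= s, with union
semantics for overlapping disks.  The full-resolution mask is then reduced
to each pyramid level.  Every annotation point is assigned to all levels, so
the reduction must be positive-preserving: the default is block max-pooling
(an output pixel is 1 iff any pixel of its block is 1); an
``area_threshold`` alternative (block mean >= 0.5) is available via
``MaskConfig.downsample``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .records import PointAnnotationSet

__all__ = [
    "MaskConfig",
    "SupervisionMaskPyramid",
    "points_to_mask",
    "downsample_mask",
    "build_supervision_pyramid",
]


@dataclass
class MaskConfig:
    radius_s: float = 75.0
    mask_size: int = 1024
    pyramid_levels: int = 4
    level_sizes: Tuple[int, ...] = (32, 64, 128, 256)
    downsample: str = "max"  # "max" | "area_threshold"

    def __post_init__(self):
        if self.radius_s <= 0:
            raise ValueError("radius_s must be > 0")
        if len(self.level_sizes) != self.pyramid_levels:
            raise ValueError("level_sizes must have pyramid_levels entries")
        if any(b <= a for a, b in zip(self.level_sizes, self.level_sizes[1:])):
            raise ValueError("level_sizes must be strictly increasing")
        for ls in self.level_sizes:
            if self.mask_size % ls != 0:
                raise ValueError(f"level size {ls} does not divide mask_size {self.mask_size}")
        if self.downsample not in ("max", "area_threshold"):
            raise ValueError("downsample must be 'max' or 'area_threshold'")

    @classmethod
    def for_input_size(cls, input_size: int, radius_at_1024: float = 75.0, **kw):
        """Desk-scale config: the disk radius scales with the working size."""
        return cls(
            radius_s=radius_at_1024 * input_size / 1024.0,
            mask_size=input_size,
            level_sizes=tuple(input_size // s for s in (32, 16, 8, 4)),
            **kw,
        )


@dataclass
class SupervisionMaskPyramid:
    """Binary masks M_1..M_K (coarse to fine) and per-level pixel counts."""

    masks: List[np.ndarray]

    @property
    def omega(self) -> List[int]:
        return [int(m.size) for m in self.masks]

    @property
    def level_sizes(self):
        return tuple(m.shape[0] for m in self.masks)

    def is_empty(self) -> bool:
        return all(m.sum() == 0 for m in self.masks)


def points_to_mask(
    points: Sequence[Tuple[float, float]], mask_size: int, radius_s: float
) -> np.ndarray:
    """Full-resolution disk mask: 1 iff within ``radius_s`` of any point."""
    if mask_size < 1:
        raise ValueError("mask_size must be >= 1")
    if radius_s <= 0:
        raise ValueError("radius_s must be > 0")
    mask = np.zeros((mask_size, mask_size), dtype=np.uint8)
    for x, y in points:
        if not (0 <= x < mask_size and 0 <= y < mask_size):
            raise ValueError(
                f"point ({x}, {y}) outside the {mask_size}x{mask_size} grid; "
                "annotations must be in preprocessed coordinates"
            )
        x0 = max(0, int(np.floor(x - radius_s)))
        x1 = min(mask_size, int(np.ceil(x + radius_s)) + 1)
        y0 = max(0, int(np.floor(y - radius_s)))
        y1 = min(mask_size, int(np.ceil(y + radius_s)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (xx - x) ** 2 + (yy - y) ** 2 <= radius_s**2
        mask[y0:y1, x0:x1] |= inside.astype(np.uint8)
    return mask


def downsample_mask(mask: np.ndarray, target_size: int, method: str = "max") -> np.ndarray:
    """Reduce a binary mask to ``target_size`` by block pooling."""
    mask = np.asarray(mask)
    side = mask.shape[0]
    if mask.shape != (side, side):
        raise ValueError("mask must be square")
    if side % target_size != 0:
        raise ValueError(
            f"target_size {target_size} does not divide mask side {side} "
            "(no fractional resampling)"
        )
    b = side // target_size
    blocks = mask.reshape(target_size, b, target_size, b)
    if method == "max":
        out = blocks.max(axis=(1, 3))
    elif method == "area_threshold":
        out = (blocks.mean(axis=(1, 3)) >= 0.5).astype(mask.dtype)
    else:
        raise ValueError("method must be 'max' or 'area_threshold'")
    return out.astype(np.uint8)


def build_supervision_pyramid(
    annotations: PointAnnotationSet, config: MaskConfig
) -> SupervisionMaskPyramid:
    """Full-resolution disk mask downsampled to every pyramid level."""
    annotations.validate_bounds(config.mask_size)
    full = points_to_mask(annotations.points, config.mask_size, config.radius_s)
    masks = [downsample_mask(full, ls, config.downsample) for ls in config.level_sizes]
    return SupervisionMaskPyramid(masks=masks)
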