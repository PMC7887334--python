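"""Stochastic training augmentation and its exact point co-transforms.

A spec fully determines an affine spatial transform (horizontal flip, then
isotropic rescale and rotation about the image center, then translation)
plus an intensity affine (multiplicative brightness, then contrast about
0.5, clipped to [0, 1]).  Annotation points are mapped through the same
spatial matrix, so image and points stay co-registered; points leaving the
canvas are dropped with a logged count.

Pixel translation ranges are specified at the 1024 px working resolution and
scale linearly for smaller inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from skimage.transform import AffineTransform, warp

from .records import ImageRecord, PointAnnotationSet

__all__ = [
    "AugmentationSpec",
    "AugmentationRanges",
    "sample_augmentation",
    "apply_augmentation",
    "spatial_matrix",
    "apply_spatial_to_map",
    "invert_spec",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AugmentationSpec:
    dx: float = 0.0
    dy: float = 0.0
    scale: float = 1.0
    hflip: bool = False
    rotation: float = 0.0  # degrees
    brightness: float = 1.0
    contrast: float = 1.0

    def is_identity(self) -> bool:
        return self == AugmentationSpec()

    def is_spatially_invertible(self) -> bool:
        return self.scale != 0


@dataclass(frozen=True)
class AugmentationRanges:
    """Uniform sampling ranges; translation in pixels at 1024 px resolution."""

    translation: float = 100.0
    scale: Tuple[float, float] = (0.9, 1.1)
    rotation: float = 15.0
    brightness: Tuple[float, float] = (0.75, 1.25)
    contrast: Tuple[float, float] = (0.75, 1.25)
    hflip_p: float = 0.5
    ref_size: int = 1024


def sample_augmentation(
    ranges: AugmentationRanges, rng: np.random.Generator, input_size: int | None = None
) -> AugmentationSpec:
    """Draw one spec, each field uniform over its configured range."""
    t = ranges.translation
    if input_size is not None:
        t = t * input_size / ranges.ref_size
    return AugmentationSpec(
        dx=float(rng.uniform(-t, t)),
        dy=float(rng.uniform(-t, t)),
        scale=float(rng.uniform(*ranges.scale)),
        hflip=bool(rng.random() < ranges.hflip_p),
        rotation=float(rng.uniform(-ranges.rotation, ranges.rotation)),
        brightness=float(rng.uniform(*ranges.brightness)),
        contrast=float(rng.uniform(*ranges.contrast)),
    )


def spatial_matrix(spec: AugmentationSpec, size: int) -> np.ndarray:
    """3x3 forward affine on (x, y) pixel-center coordinates."""
    c = (size - 1) / 2.0
    flip = np.array([[-1.0, 0, size - 1.0], [0, 1, 0], [0, 0, 1]]) if spec.hflip else np.eye(3)
    th = np.deg2rad(spec.rotation)
    rs = np.array(
        [
            [spec.scale * np.cos(th), -spec.scale * np.sin(th), 0.0],
            [spec.scale * np.sin(th), spec.scale * np.cos(th), 0.0],
            [0, 0, 1],
        ]
    )
    center = np.array([[1.0, 0, -c], [0, 1, -c], [0, 0, 1]])
    uncenter = np.array([[1.0, 0, c], [0, 1, c], [0, 0, 1]])
    trans = np.array([[1.0, 0, spec.dx], [0, 1, spec.dy], [0, 0, 1]])
    return trans @ uncenter @ rs @ center @ flip


def _warp_image(pixels: np.ndarray, matrix: np.ndarray, cval: float) -> np.ndarray:
    tform = AffineTransform(matrix=matrix)
    return warp(
        pixels.astype(np.float64), tform.inverse, order=1, cval=cval,
        mode="constant", preserve_range=True,
    )


def apply_augmentation(
    image: ImageRecord, points: PointAnnotationSet, spec: AugmentationSpec
) -> Tuple[ImageRecord, PointAnnotationSet]:
    """Transform an image and its annotation points together."""
    size = image.size
    m = spatial_matrix(spec, size)
    if spec == AugmentationSpec():
        out = image.pixels.astype(np.float64)
    else:
        out = _warp_image(image.pixels, m, cval=0.0)
        out = out * spec.brightness
        out = (out - 0.5) * spec.contrast + 0.5
        out = np.clip(out, 0.0, 1.0)
    new_points, new_cats = [], []
    cats = points.categories or [None] * len(points.points)
    dropped = 0
    for (x, y), cat in zip(points.points, cats):
        tx, ty, _ = m @ np.array([x, y, 1.0])
        if 0 <= tx < size and 0 <= ty < size:
            new_points.append((float(tx), float(ty)))
            new_cats.append(cat)
        else:
            dropped += 1
    if dropped:
        logger.info("augmentation dropped %d point(s) leaving the canvas", dropped)
    rec = ImageRecord(
        pixels=out.astype(np.float32),
        image_id=image.image_id,
        original_size=image.original_size,
        pad=image.pad,
        scale=image.scale,
    )
    ann = PointAnnotationSet(
        image_id=points.image_id,
        points=new_points,
        categories=[c for c in new_cats] if points.categories is not None else None,
    )
    return rec, ann


def invert_spec(spec: AugmentationSpec) -> AugmentationSpec:
    """Spatial inverse of a flip/rotation(/scale) spec.

    Only valid for specs without translation (the TTA families); intensity
    components are dropped (they have no spatial effect).
    """
    if spec.dx or spec.dy:
        raise ValueError("invert_spec only supports translation-free specs")
    # forward = R(theta) S(s) F ; inverse = F R(-theta') S(1/s) with the flip
    # conjugation absorbed by negating the angle twice -> same angle sign flip
    if not spec.hflip:
        return AugmentationSpec(scale=1.0 / spec.scale, rotation=-spec.rotation)
    # F^-1 (RS)^-1 = F S^-1 R(-th); conjugating through F: R(th') F with th' = th
    return AugmentationSpec(scale=1.0 / spec.scale, rotation=spec.rotation, hflip=True)


def apply_spatial_to_map(grid: np.ndarray, spec: AugmentationSpec, cval: float) -> np.ndarray:
    """Apply a spec's spatial part to a saliency grid at its own resolution."""
    size = grid.shape[0]
    m = spatial_matrix(replace(spec, brightness=1.0, contrast=1.0, dx=0.0, dy=0.0), size)
    if np.allclose(m, np.eye(3)):
        return grid.copy()
    return _warp_image(grid, m, cval=cval)
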