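"""Bagged test-time-augmentation ensemble inference.

Each of the cross-validation fold models scores several augmented copies of
the input (horizontal flip, rotation and contrast families only).  Every
member map is the sigmoid of the model's output-level saliency logits; the
image-level probability is the mean over members of each member's maximum
pixel value, and the localization map is the pixel-wise mean of the member
maps after inverse-transforming them back into input alignment.

Out-of-support pixels created by inverse rotation are filled with the map's
minimum, not zero, so borders do not masquerade as confident negatives in
sigmoid space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
from skimage.transform import resize

from .augment import AugmentationSpec, apply_augmentation, apply_spatial_to_map, invert_spec
from .detector import DetectorModel, forward_saliency
from .records import ImageRecord, PointAnnotationSet

__all__ = ["TTAConfig", "EnsembleOutput", "ensemble_predict", "invert_augmentation", "render_overlay"]


@dataclass
class TTAConfig:
    """Predefined augmentations applied at inference (first is identity)."""

    specs: List[AugmentationSpec] = field(default_factory=lambda: [AugmentationSpec()])

    def __post_init__(self):
        if not self.specs:
            raise ValueError("TTAConfig needs at least one spec")
        if not self.specs[0].is_identity():
            raise ValueError("the first TTA spec must be the identity")
        for s in self.specs:
            if s.dx or s.dy or s.scale != 1.0:
                raise ValueError("TTA specs may only use flip, rotation and contrast")

    @classmethod
    def default(cls) -> "TTAConfig":
        return cls(
            specs=[
                AugmentationSpec(),
                AugmentationSpec(hflip=True),
                AugmentationSpec(rotation=10.0),
                AugmentationSpec(rotation=-10.0),
                AugmentationSpec(contrast=1.15),
            ]
        )


@dataclass
class EnsembleOutput:
    probability: float
    member_maps: List[np.ndarray]  # sigmoid maps as produced, pre-alignment
    fused_map: np.ndarray  # mean of inverse-transformed member maps
    n_members: int


def invert_augmentation(saliency_map: np.ndarray, spec: AugmentationSpec) -> np.ndarray:
    """Spatially realign a member map with the un-augmented input."""
    if not spec.is_spatially_invertible():
        raise ValueError("spec is not spatially invertible")
    inv = invert_spec(spec)
    if inv.is_identity() or (not inv.hflip and inv.rotation == 0.0 and inv.scale == 1.0):
        return np.asarray(saliency_map, dtype=np.float64).copy()
    return apply_spatial_to_map(
        np.asarray(saliency_map, dtype=np.float64), inv, cval=float(np.min(saliency_map))
    )


def ensemble_predict(
    models: Sequence[DetectorModel], image: ImageRecord, tta: TTAConfig
) -> EnsembleOutput:
    """Bagged TTA prediction: p = (1/N) sum_n max_ij sigmoid(P^n(i, j))."""
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    ref = models[0].config
    for m in models[1:]:
        if (
            m.config.input_size != ref.input_size
            or m.config.output_level != ref.output_level
            or m.config.backbone != ref.backbone
        ):
            raise ValueError("ensemble models must share backbone, input_size and output_level")
    img = image if isinstance(image, ImageRecord) else ImageRecord(pixels=np.asarray(image))
    empty = PointAnnotationSet(image_id=img.image_id)
    member_maps: List[np.ndarray] = []
    aligned: List[np.ndarray] = []
    for spec in tta.specs:
        aug_img, _ = apply_augmentation(img, empty, spec)
        for model in models:
            pyr = forward_saliency(model, aug_img)
            logits = pyr.output_map(ref.output_level)
            smap = 1.0 / (1.0 + np.exp(-logits))
            member_maps.append(smap)
            aligned.append(invert_augmentation(smap, spec))
    p = float(np.mean([m.max() for m in member_maps]))
    fused = np.mean(aligned, axis=0)
    return EnsembleOutput(
        probability=p, member_maps=member_maps, fused_map=fused, n_members=len(member_maps)
    )


def fused_peak_location(fused_map: np.ndarray, image_size: int):
    """(x, y) image coordinates of the fused map's maximum (pixel centers)."""
    fm = np.asarray(fused_map)
    i, j = np.unravel_index(int(np.argmax(fm)), fm.shape)
    stride = image_size / fm.shape[0]
    return ((j + 0.5) * stride - 0.5, (i + 0.5) * stride - 0.5)


def render_overlay(image: ImageRecord, fused_map: np.ndarray, out_path) -> Path:
    """Write the localization map over the image as a red-emphasis PNG."""
    img = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    size = img.shape[0]
    m = np.clip(np.asarray(fused_map, dtype=np.float64), 0.0, 1.0)
    if m.shape != img.shape:
        m = resize(m, img.shape, order=1, mode="edge", anti_aliasing=False)
    alpha = 0.6 * m
    gray = np.clip(img.astype(np.float64), 0.0, 1.0)
    rgb = np.empty((size, img.shape[1], 3), dtype=np.float64)
    rgb[..., 0] = gray * (1 - alpha) + alpha  # red emphasis
    rgb[..., 1] = gray * (1 - alpha)
    rgb[..., 2] = gray * (1 - alpha)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    import imageio.v3 as iio

    iio.imwrite(out_path, np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    return out_path
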