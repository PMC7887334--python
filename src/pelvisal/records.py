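"""Core data records shared across the pipeline.

Coordinate convention (used everywhere in this package): x = column,
y = row, 0-based, origin at the top-left, with points located at pixel
centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["ImageRecord", "PointAnnotationSet"]


@dataclass
class ImageRecord:
    """A preprocessed square grayscale image with provenance.

    ``pad`` records the (left, top) zero-padding applied to the raw image
    before resizing and ``scale`` the resize factor from padded to final
    pixels, so raw-coordinate annotations can be mapped forward.
    """

    pixels: np.ndarray
    image_id: str = ""
    original_size: Tuple[int, int] = (0, 0)  # (height, width) of the raw image
    pad: Tuple[int, int] = (0, 0)  # (left, top) zero-padding in raw pixels
    scale: float = 1.0  # final_size / padded_side

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("ImageRecord.pixels must be a 2-D array")
        if self.original_size == (0, 0):
            self.original_size = self.pixels.shape

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def map_raw_points(self, points: Sequence[Tuple[float, float]]):
        """Map raw-image (x, y) points into preprocessed coordinates.

        Pixel-center convention: raw center x maps to
        ``(x + pad_left + 0.5) * scale - 0.5``.  Results are clamped into the
        valid pixel-coordinate range [0, size) so that corner annotations on
        downscaled images remain usable as mask centers.
        """
        left, top = self.pad
        s = self.scale
        hi = self.size - 1e-6
        return [
            (
                float(np.clip((x + left + 0.5) * s - 0.5, 0.0, hi)),
                float(np.clip((y + top + 0.5) * s - 0.5, 0.0, hi)),
            )
            for x, y in points
        ]


@dataclass
class PointAnnotationSet:
    """Per-image lesion points (preprocessed coordinates) with categories."""

    image_id: str
    points: List[Tuple[float, float]] = field(default_factory=list)
    categories: Optional[List[str]] = None

    def __post_init__(self):
        self.points = [(float(x), float(y)) for x, y in self.points]
        if self.categories is not None and len(self.categories) != len(self.points):
            raise ValueError("categories must parallel points")

    def __len__(self):
        return len(self.points)

    @property
    def is_positive(self) -> bool:
        return len(self.points) > 0

    def validate_bounds(self, image_size: int):
        for x, y in self.points:
            if not (0 <= x < image_size and 0 <= y < image_size):
                raise ValueError(
                    f"annotation point ({x}, {y}) outside [0, {image_size}) "
                    f"for image {self.image_id!r}"
                )
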