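"""Image standardization: zero-pad to square, resize, record the transform."""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .records import ImageRecord

__all__ = ["preprocess_image"]


def preprocess_image(raw_image, target_size: int, image_id: str = "") -> ImageRecord:
    """Pad the short axis symmetrically with zeros to square, then resize.

    The pad offsets and resize scale are recorded on the returned record so
    raw-coordinate annotations can be mapped into preprocessed coordinates.
    An odd padding deficit puts the extra pixel on the bottom/right.
    """
    raw = np.asarray(raw_image, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"raw image must be 2-D and nonempty, got shape {raw.shape}")
    if target_size < 1:
        raise ValueError("target_size must be positive")
    h, w = raw.shape
    side = max(h, w)
    pad_top = (side - h) // 2
    pad_left = (side - w) // 2
    padded = np.zeros((side, side), dtype=np.float64)
    padded[pad_top : pad_top + h, pad_left : pad_left + w] = raw
    if side == target_size:
        out = padded
    else:
        out = resize(padded, (target_size, target_size), order=1, mode="constant",
                     anti_aliasing=side > target_size)
    return ImageRecord(
        pixels=np.clip(out, 0.0, 1.0).astype(np.float32),
        image_id=image_id,
        original_size=(h, w),
        pad=(pad_left, pad_top),
        scale=target_size / side,
    )
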