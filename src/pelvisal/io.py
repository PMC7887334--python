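"""Reading and writing the package's external formats.

Images are single-channel PNG, 8-bit by default (16-bit accepted on read).
Annotations are JSON-lines, one object per image:
``{"image": "<relative path>", "points": [[x, y], ...], "categories": [...]}``
with empty lists for negative images.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import imageio.v3 as iio
import numpy as np

from .records import PointAnnotationSet

__all__ = [
    "read_image",
    "write_image",
    "write_annotations",
    "read_annotations",
]


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG into a float array in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # accept RGB(A) by taking the first channel
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def write_image(path, pixels: np.ndarray):
    """Write a float image in [0, 1] as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(pixels), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def _annotation_obj(rel_path: str, ann: PointAnnotationSet) -> str:
    obj = {
        "image": rel_path,
        "points": [[round(float(x), 4), round(float(y), 4)] for x, y in ann.points],
        "categories": list(ann.categories) if ann.categories else [],
    }
    return json.dumps(obj, separators=(", ", ": "))


def write_annotations(path, entries: List[tuple]):
    """Write (relative path, PointAnnotationSet) pairs as JSON-lines."""
    lines = [_annotation_obj(rel, ann) for rel, ann in entries]
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path) -> List[tuple]:
    """Read JSON-lines annotations back as (relative path, PointAnnotationSet)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        ann = PointAnnotationSet(
            image_id=obj["image"],
            points=[tuple(p) for p in obj["points"]],
            categories=obj.get("categories") or None if obj.get("points") else None,
        )
        out.append((obj["image"], ann))
    return out
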