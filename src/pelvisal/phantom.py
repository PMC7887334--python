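"""Synthetic pelvis-like phantom radiographs with insertable lesions.

The phantom is deliberately schematic: a bright pelvic-ring annulus plus two
femur primitives (head disk + shaft capsule) on a darker background, with
Gaussian smoothing and additive noise.  It provides exactly the structure a
point-supervised detector needs to be testable — bright bone edges that a
lesion renderer can disrupt — and makes no claim of anatomical realism.

Each lesion category has one distinguishable appearance:

* ``fracture_line`` — a dark, slightly wiggly polyline crossing bone;
* ``fracture_gap`` — a wider dark band, as if a segment were displaced;
* ``dislocation`` — a bright ring (displaced femoral-head rim) with a dark
  core adjacent to it;
* ``periprosthetic`` — a bright implant bar with an adjacent dark line;
* ``shaft_fracture`` — a straight dark line across the femoral shaft.

All lesion pixel modifications are confined to a disk of radius
``lesion_support_radius(image_size)`` around the anchor, and the annotation
point is the anchor itself, mirroring point-at-the-finding-center labelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import write_annotations, write_image
from .records import ImageRecord, PointAnnotationSet

__all__ = [
    "LESION_CATEGORIES",
    "PhantomConfig",
    "LesionSpec",
    "DatasetManifest",
    "lesion_support_radius",
    "generate_phantom",
    "inject_lesions",
    "sample_lesion_specs",
    "generate_dataset",
    "load_manifest",
]

LESION_CATEGORIES = (
    "fracture_line",
    "fracture_gap",
    "dislocation",
    "periprosthetic",
    "shaft_fracture",
)

# point-count distribution for positive images (median 1, range 1..7)
_POINT_COUNTS = np.arange(1, 8)
_POINT_PROBS = np.array([0.62, 0.20, 0.09, 0.045, 0.025, 0.012, 0.008])


@dataclass
class RingGeometry:
    """Pelvis-like annulus, in fractions of the image side."""

    center: Tuple[float, float] = (0.5, 0.40)  # (x, y)
    r_outer: float = 0.30
    r_inner: float = 0.20


@dataclass
class FemurGeometry:
    """One femur: head disk plus a shaft capsule, relative units."""

    head_center: Tuple[float, float] = (0.28, 0.55)
    head_radius: float = 0.07
    shaft_end: Tuple[float, float] = (0.20, 0.94)
    shaft_halfwidth: float = 0.035


@dataclass
class PhantomConfig:
    image_size: int = 256
    bone_intensity: float = 0.85
    background_intensity: float = 0.25
    ring_geometry: RingGeometry = field(default_factory=RingGeometry)
    femur_geometry: Tuple[FemurGeometry, FemurGeometry] = field(
        default_factory=lambda: (
            FemurGeometry(),
            FemurGeometry(head_center=(0.72, 0.55), shaft_end=(0.80, 0.94)),
        )
    )
    noise_sd: float = 0.02
    blur_sigma: float = 1.5
    geometry_jitter: float = 0.015  # relative sd of per-image geometry wobble

    def __post_init__(self):
        if self.image_size < 64 or self.image_size % 32 != 0:
            raise ValueError("image_size must be >= 64 and divisible by 32")
        if not (0.0 <= self.background_intensity < self.bone_intensity <= 1.0):
            raise ValueError(
                "require 0 <= background_intensity < bone_intensity <= 1"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self._validate_geometry()

    def _validate_geometry(self):
        cx, cy = self.ring_geometry.center
        r = self.ring_geometry.r_outer
        if self.ring_geometry.r_inner >= r:
            raise ValueError("ring_geometry: r_inner must be < r_outer")
        if not (0 < cx - r and cx + r < 1 and 0 < cy - r and cy + r < 1):
            raise ValueError("ring_geometry: annulus extends outside the canvas")
        for i, f in enumerate(self.femur_geometry):
            checks = (
                ("head_center", f.head_center, f.head_radius),
                ("shaft_end", f.shaft_end, f.shaft_halfwidth),
            )
            for name, (px, py), m in checks:
                if not (0 <= px - m and px + m <= 1 and 0 <= py - m and py + m <= 1.0):
                    raise ValueError(f"femur_geometry[{i}].{name}: primitive outside canvas")


@dataclass
class LesionSpec:
    category: str
    anchor: Tuple[float, float]  # (x, y) pixels, on a bone primitive
    magnitude: float = 0.6  # severity scalar in (0, 1]
    orientation: float = 0.0  # degrees

    def __post_init__(self):
        if self.category not in LESION_CATEGORIES:
            raise ValueError(
                f"unknown lesion category {self.category!r}; expected one of {LESION_CATEGORIES}"
            )
        if not (0 < self.magnitude <= 1):
            raise ValueError("magnitude must lie in (0, 1]")


@dataclass
class ManifestRecord:
    path: str
    annotations: PointAnnotationSet
    split: str = "train"


@dataclass
class DatasetManifest:
    records: List[ManifestRecord]
    seed: int
    positive_fraction: float
    root: str = "."

    def __len__(self):
        return len(self.records)

    @property
    def n_positive(self):
        return sum(1 for r in self.records if r.annotations.is_positive)

    def image_path(self, record: ManifestRecord) -> Path:
        return Path(self.root) / record.path


def lesion_support_radius(image_size: int) -> float:
    """Radius (pixels) of the disk around an anchor that a lesion may touch."""
    return 16.0 * image_size / 256.0


# ---------------------------------------------------------------------------
# geometry + rendering

def _jittered_geometry(config: PhantomConfig, rng: np.random.Generator):
    j = config.geometry_jitter

    def wob(v):
        return v + rng.normal(0.0, j) if j > 0 else v

    ring = RingGeometry(
        center=(wob(config.ring_geometry.center[0]), wob(config.ring_geometry.center[1])),
        r_outer=max(0.05, wob(config.ring_geometry.r_outer)),
        r_inner=max(0.02, wob(config.ring_geometry.r_inner)),
    )
    femurs = []
    for f in config.femur_geometry:
        femurs.append(
            FemurGeometry(
                head_center=(wob(f.head_center[0]), wob(f.head_center[1])),
                head_radius=max(0.02, wob(f.head_radius)),
                shaft_end=(wob(f.shaft_end[0]), min(0.94, wob(f.shaft_end[1]))),
                shaft_halfwidth=max(0.01, wob(f.shaft_halfwidth)),
            )
        )
    return ring, femurs


def _segment_distance(xx, yy, p0, p1):
    """Distance from each grid point to the segment p0-p1 (pixel coords)."""
    px, py = p1[0] - p0[0], p1[1] - p0[1]
    norm2 = px * px + py * py
    if norm2 == 0:
        return np.hypot(xx - p0[0], yy - p0[1])
    t = np.clip(((xx - p0[0]) * px + (yy - p0[1]) * py) / norm2, 0.0, 1.0)
    return np.hypot(xx - (p0[0] + t * px), yy - (p0[1] + t * py))


def _bone_mask(config: PhantomConfig, ring, femurs):
    s = config.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cx, cy = ring.center[0] * s, ring.center[1] * s
    d = np.hypot(xx - cx, yy - cy)
    mask = (d >= ring.r_inner * s) & (d <= ring.r_outer * s)
    for f in femurs:
        hc = (f.head_center[0] * s, f.head_center[1] * s)
        se = (f.shaft_end[0] * s, f.shaft_end[1] * s)
        mask |= np.hypot(xx - hc[0], yy - hc[1]) <= f.head_radius * s
        mask |= _segment_distance(xx, yy, hc, se) <= f.shaft_halfwidth * s
    return mask


def generate_phantom(config: PhantomConfig, seed: int) -> ImageRecord:
    """Render one lesion-free phantom; deterministic given (config, seed)."""
    rng = np.random.default_rng(seed)
    ring, femurs = _jittered_geometry(config, rng)
    mask = _bone_mask(config, ring, femurs)
    img = np.where(mask, config.bone_intensity, config.background_intensity)
    if config.blur_sigma > 0:
        img = gaussian_filter(img, config.blur_sigma, mode="nearest")
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    rec = ImageRecord(pixels=img, image_id=f"phantom_{seed}")
    rec.geometry = (ring, femurs)  # carried for lesion placement
    return rec


# ---------------------------------------------------------------------------
# lesion rendering

def _local_window(img, anchor, radius):
    s = img.shape[0]
    x0 = max(0, int(math.floor(anchor[0] - radius)))
    x1 = min(s, int(math.ceil(anchor[0] + radius)) + 1)
    y0 = max(0, int(math.floor(anchor[1] - radius)))
    y1 = min(s, int(math.ceil(anchor[1] + radius)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    return (slice(y0, y1), slice(x0, x1)), xx, yy


def _soft_line(xx, yy, p0, p1, width):
    d = _segment_distance(xx, yy, p0, p1)
    return np.clip(1.0 + 0.8 * width - d / max(width, 1e-6) * width * 1.0, 0.0, 1.0) * (
        d <= width * 1.8
    )


def _paint(img, window, weight, amount):
    """Add ``amount * weight`` inside the window, clipped to [0, 1]."""
    sl = window
    img[sl] = np.clip(img[sl] + amount * weight, 0.0, 1.0)


def _render_lesion(img, spec: LesionSpec, rng: np.random.Generator):
    s = img.shape[0]
    scale = s / 256.0
    support = lesion_support_radius(s)
    ax, ay = spec.anchor
    theta = math.radians(spec.orientation)
    ux, uy = math.cos(theta), math.sin(theta)  # lesion axis
    amp = 0.55 * spec.magnitude
    window, xx, yy = _local_window(img, spec.anchor, support)

    def clamp_pt(px, py):
        # keep endpoints inside the support disk
        dx, dy = px - ax, py - ay
        r = math.hypot(dx, dy)
        m = support - 1.0
        if r > m:
            px, py = ax + dx / r * m, ay + dy / r * m
        return px, py

    cat = spec.category
    if cat in ("fracture_line", "shaft_fracture"):
        half = (12.0 if cat == "fracture_line" else 9.0) * scale
        width = (1.2 if cat == "fracture_line" else 1.6) * scale
        if cat == "fracture_line":
            # slightly wiggly polyline through the anchor
            mid_off = rng.normal(0.0, 1.2 * scale)
            p0 = clamp_pt(ax - ux * half, ay - uy * half)
            p2 = clamp_pt(ax + ux * half, ay + uy * half)
            pm = (ax - uy * mid_off, ay + ux * mid_off)
            w = np.maximum(_soft_line(xx, yy, p0, pm, width), _soft_line(xx, yy, pm, p2, width))
        else:
            p0 = clamp_pt(ax - ux * half, ay - uy * half)
            p2 = clamp_pt(ax + ux * half, ay + uy * half)
            w = _soft_line(xx, yy, p0, p2, width)
        _paint(img, window, w, -amp)
    elif cat == "fracture_gap":
        half = 8.0 * scale
        p0 = clamp_pt(ax - ux * half, ay - uy * half)
        p2 = clamp_pt(ax + ux * half, ay + uy * half)
        w = _soft_line(xx, yy, p0, p2, 2.6 * scale)
        _paint(img, window, w, -amp)
        # faint bright displaced edge alongside the gap
        off = 4.0 * scale
        q0 = clamp_pt(p0[0] - uy * off, p0[1] + ux * off)
        q2 = clamp_pt(p2[0] - uy * off, p2[1] + ux * off)
        _paint(img, window, _soft_line(xx, yy, q0, q2, 1.0 * scale), 0.35 * amp)
    elif cat == "dislocation":
        r_rim = 7.0 * scale
        d = np.hypot(xx - ax, yy - ay)
        rim = np.clip(1.0 - np.abs(d - r_rim) / (1.6 * scale), 0.0, 1.0)
        _paint(img, window, rim, amp)  # bright displaced head rim
        core = np.clip(1.0 - d / (3.0 * scale), 0.0, 1.0)
        _paint(img, window, core, -0.7 * amp)  # vacated socket
    elif cat == "periprosthetic":
        half = 9.0 * scale
        p0 = clamp_pt(ax - ux * half, ay - uy * half)
        p2 = clamp_pt(ax + ux * half, ay + uy * half)
        _paint(img, window, _soft_line(xx, yy, p0, p2, 2.2 * scale), amp)  # implant
        off = 4.5 * scale
        q0 = clamp_pt(p0[0] - uy * off, p0[1] + ux * off)
        q2 = clamp_pt(p2[0] - uy * off, p2[1] + ux * off)
        _paint(img, window, _soft_line(xx, yy, q0, q2, 1.2 * scale), -amp)


def inject_lesions(
    image: ImageRecord, specs: Sequence[LesionSpec], seed: int
) -> Tuple[ImageRecord, PointAnnotationSet]:
    """Render lesions into a phantom; one annotation point per spec.

    An empty spec list returns the image unchanged with an empty annotation
    set (a negative example).
    """
    s = image.size
    for spec in specs:
        x, y = spec.anchor
        if not (0 <= x < s and 0 <= y < s):
            raise ValueError(f"lesion anchor {spec.anchor} outside image bounds [0, {s})")
    img = image.pixels.astype(np.float64).copy()
    rng = np.random.default_rng(seed)
    for spec in specs:
        _render_lesion(img, spec, rng)
    out = ImageRecord(
        pixels=img.astype(np.float32),
        image_id=image.image_id,
        original_size=image.original_size,
        pad=image.pad,
        scale=image.scale,
    )
    ann = PointAnnotationSet(
        image_id=image.image_id,
        points=[spec.anchor for spec in specs],
        categories=[spec.category for spec in specs] if specs else None,
    )
    return out, ann


# ---------------------------------------------------------------------------
# lesion placement

def sample_lesion_specs(
    config: PhantomConfig, geometry, k: int, rng: np.random.Generator
) -> List[LesionSpec]:
    """Draw ``k`` lesion specs anchored on the phantom's bone primitives."""
    ring, femurs = geometry
    s = config.image_size
    margin = lesion_support_radius(s) + 1.0
    specs = []
    for _ in range(k):
        site = rng.choice(["ring", "head", "shaft"], p=[0.5, 0.25, 0.25])
        if site == "ring":
            angle = rng.uniform(0, 2 * math.pi)
            r = rng.uniform(ring.r_inner + 0.01, ring.r_outer - 0.01) * s
            ax = ring.center[0] * s + r * math.cos(angle)
            ay = ring.center[1] * s + r * math.sin(angle)
            category = rng.choice(["fracture_line", "fracture_gap", "periprosthetic"],
                                  p=[0.6, 0.25, 0.15])
        elif site == "head":
            f = femurs[int(rng.integers(len(femurs)))]
            ax, ay = f.head_center[0] * s, f.head_center[1] * s
            category = rng.choice(["dislocation", "fracture_line"], p=[0.5, 0.5])
        else:
            f = femurs[int(rng.integers(len(femurs)))]
            t = rng.uniform(0.25, 0.75)
            hc = (f.head_center[0] * s, f.head_center[1] * s)
            se = (f.shaft_end[0] * s, f.shaft_end[1] * s)
            ax = hc[0] + t * (se[0] - hc[0])
            ay = hc[1] + t * (se[1] - hc[1])
            category = "shaft_fracture"
        ax = float(np.clip(ax, margin, s - margin))
        ay = float(np.clip(ay, margin, s - margin))
        specs.append(
            LesionSpec(
                category=str(category),
                anchor=(ax, ay),
                magnitude=float(rng.uniform(0.5, 0.95)),
                orientation=float(rng.uniform(0.0, 180.0)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# dataset generation

def generate_dataset(
    n: int,
    positive_fraction: float,
    config: PhantomConfig,
    seed: int,
    out_dir,
    split: str = "train",
) -> DatasetManifest:
    """Write ``n`` phantom PNGs plus a JSON-lines annotation file.

    Fully reproducible from ``(n, positive_fraction, config, seed)``; positive
    images carry 1–7 lesion points (median 1), negatives none.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError("positive_fraction must lie in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    records = []
    entries = []
    for i in range(n):
        img_seed = int(master.integers(2**31))
        positive = bool(master.random() < positive_fraction)
        k = int(master.choice(_POINT_COUNTS, p=_POINT_PROBS)) if positive else 0
        rec = generate_phantom(config, img_seed)
        rng = np.random.default_rng(img_seed + 1)
        specs = sample_lesion_specs(config, rec.geometry, k, rng) if k else []
        img, ann = inject_lesions(rec, specs, seed=img_seed + 2)
        rel = f"img_{i:05d}.png"
        ann.image_id = rel
        write_image(out_dir / rel, img.pixels)
        records.append(ManifestRecord(path=rel, annotations=ann, split=split))
        entries.append((rel, ann))
    write_annotations(out_dir / "annotations.jsonl", entries)
    return DatasetManifest(
        records=records, seed=seed, positive_fraction=positive_fraction, root=str(out_dir)
    )


def load_manifest(directory, split: str = "train") -> DatasetManifest:
    """Load a generated dataset directory back into a manifest."""
    from .io import read_annotations

    directory = Path(directory)
    entries = read_annotations(directory / "annotations.jsonl")
    records = [
        ManifestRecord(path=rel, annotations=ann, split=split) for rel, ann in entries
    ]
    n_pos = sum(1 for r in records if r.annotations.is_positive)
    return DatasetManifest(
        records=records,
        seed=-1,
        positive_fraction=n_pos / max(1, len(records)),
        root=str(directory),
    )
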