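"""Phantom generation, lesion injection and dataset reproducibility."""

from pathlib import Path

import numpy as np
import pytest

from pelvisal.phantom import (
    LESION_CATEGORIES,
    FemurGeometry,
    LesionSpec,
    PhantomConfig,
    RingGeometry,
    generate_dataset,
    generate_phantom,
    inject_lesions,
    lesion_support_radius,
    load_manifest,
    sample_lesion_specs,
    _bone_mask,
)


def test_generate_phantom_deterministic(small_phantom_config):
    a = generate_phantom(small_phantom_config, seed=7)
    b = generate_phantom(small_phantom_config, seed=7)
    np.testing.assert_array_equal(a.pixels, b.pixels)


def test_noiseless_phantom_has_only_configured_intensities():
    cfg = PhantomConfig(image_size=128, noise_sd=0.0, blur_sigma=0.0)
    rec = generate_phantom(cfg, seed=0)
    values = set(np.unique(rec.pixels))
    assert values <= {np.float32(cfg.background_intensity), np.float32(cfg.bone_intensity)}


def test_ring_region_brighter_than_background(small_phantom_config):
    """Region-mean oracle: mask the annulus directly from the drawn geometry
    and compare mean intensities inside vs outside all bone."""
    rec = generate_phantom(small_phantom_config, seed=1)
    ring, femurs = rec.geometry
    s = small_phantom_config.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    d = np.hypot(xx - ring.center[0] * s, yy - ring.center[1] * s)
    ring_mask = (d >= ring.r_inner * s) & (d <= ring.r_outer * s)
    bone = _bone_mask(small_phantom_config, ring, femurs)
    assert rec.pixels[ring_mask].mean() > rec.pixels[~bone].mean() + 0.2


def test_invalid_geometry_names_offending_field():
    with pytest.raises(ValueError, match="ring_geometry"):
        PhantomConfig(image_size=128, ring_geometry=RingGeometry(center=(0.9, 0.4)))
    with pytest.raises(ValueError, match="femur_geometry"):
        PhantomConfig(
            image_size=128,
            femur_geometry=(FemurGeometry(shaft_end=(0.0, 0.94)), FemurGeometry()),
        )


def test_inject_no_lesions_is_identity(small_phantom_config):
    rec = generate_phantom(small_phantom_config, seed=3)
    out, ann = inject_lesions(rec, [], seed=0)
    np.testing.assert_array_equal(out.pixels, rec.pixels)
    assert len(ann) == 0 and not ann.is_positive


@pytest.mark.parametrize("category", LESION_CATEGORIES)
def test_lesion_modifies_only_near_anchor(small_phantom_config, category):
    """Pixel-diff oracle: every changed pixel lies inside the lesion support
    disk (well within twice the scaled supervision radius), and at least one
    pixel changes."""
    rec = generate_phantom(small_phantom_config, seed=4)
    s = small_phantom_config.image_size
    anchor = (s * 0.5, s * 0.4)
    spec = LesionSpec(category=category, anchor=anchor, magnitude=0.8, orientation=30.0)
    out, ann = inject_lesions(rec, [spec], seed=1)
    assert ann.points == [anchor]
    diff = np.abs(out.pixels.astype(np.float64) - rec.pixels.astype(np.float64))
    changed = np.argwhere(diff > 0)
    assert len(changed) >= 1
    dists = np.hypot(changed[:, 1] - anchor[0], changed[:, 0] - anchor[1])
    mask_radius = 75.0 * s / 1024.0
    assert dists.max() <= 2 * mask_radius
    assert dists.max() <= lesion_support_radius(s)


def test_seven_lesions_give_seven_points(small_phantom_config):
    rec = generate_phantom(small_phantom_config, seed=5)
    rng = np.random.default_rng(0)
    specs = sample_lesion_specs(small_phantom_config, rec.geometry, 7, rng)
    out, ann = inject_lesions(rec, specs, seed=2)
    assert len(ann) == 7
    assert len(ann.categories) == 7


def test_all_negative_dataset(tmp_path, small_phantom_config):
    man = generate_dataset(10, 0.0, small_phantom_config, seed=0, out_dir=tmp_path)
    assert len(man) == 10
    assert man.n_positive == 0
    assert all(len(r.annotations) == 0 for r in man.records)
    assert all((tmp_path / r.path).exists() for r in man.records)


def test_positive_count_within_binomial_interval(tmp_path, small_phantom_config):
    """n=200 at 33% positives: the count must fall in the central 99%
    binomial interval (56, 76)."""
    man = generate_dataset(200, 0.33, small_phantom_config, seed=3, out_dir=tmp_path)
    assert 56 <= man.n_positive <= 76
    counts = [len(r.annotations) for r in man.records]
    assert max(counts) <= 7


def test_dataset_regeneration_byte_identical(tmp_path, small_phantom_config):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_dataset(20, 0.5, small_phantom_config, seed=11, out_dir=d1)
    generate_dataset(20, 0.5, small_phantom_config, seed=11, out_dir=d2)
    assert (d1 / "annotations.jsonl").read_bytes() == (d2 / "annotations.jsonl").read_bytes()
    assert (d1 / "img_00000.png").read_bytes() == (d2 / "img_00000.png").read_bytes()


def test_manifest_roundtrip(small_dataset):
    loaded = load_manifest(small_dataset.root)
    assert len(loaded) == len(small_dataset)
    for a, b in zip(loaded.records, small_dataset.records):
        assert a.path == b.path
        assert len(a.annotations) == len(b.annotations)
        for (x1, y1), (x2, y2) in zip(a.annotations.points, b.annotations.points):
            assert abs(x1 - x2) < 1e-3 and abs(y1 - y2) < 1e-3


def test_annotation_points_inside_lesion_support(small_dataset):
    """Localization truth: regenerating any positive image without its
    lesions leaves differences only near the annotated points."""
    from pelvisal.io import read_image

    cfg = PhantomConfig(image_size=128)
    rec = next(r for r in small_dataset.records if r.annotations.is_positive)
    img = read_image(Path(small_dataset.root) / rec.path)
    support = lesion_support_radius(cfg.image_size)
    for x, y in rec.annotations.points:
        assert 0 <= x < cfg.image_size and 0 <= y < cfg.image_size
        win = img[
            max(0, int(y - 3)) : int(y + 4), max(0, int(x - 3)) : int(x + 4)
        ]
        assert win.size > 0
    assert support < cfg.image_size
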