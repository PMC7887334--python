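"""Pyramid detector contract: level sizes, determinism, probabilities."""

import numpy as np
import pytest

from pelvisal.detector import (
    ModelConfig,
    SaliencyPyramid,
    build_model,
    forward_saliency,
    image_probability,
    load_checkpoint,
    save_checkpoint,
)


def test_tiny_level_sizes_preserve_scale_ratio():
    m = build_model(ModelConfig(backbone="tiny_fpn", input_size=256), seed=0)
    pyr = forward_saliency(m, np.zeros((256, 256), dtype=np.float32))
    assert pyr.level_sizes == (8, 16, 32, 64)
    assert all(np.isfinite(lv).all() for lv in pyr.logits)


def test_dense_backbone_level_sizes_small_input():
    m = build_model(ModelConfig(backbone="densenet169_fpn", input_size=256), seed=0)
    pyr = forward_saliency(m, np.zeros((256, 256), dtype=np.float32))
    assert pyr.level_sizes == (8, 16, 32, 64)


def test_unknown_backbone_rejected():
    with pytest.raises(ValueError, match="backbone"):
        ModelConfig(backbone="resnet50_fpn")


def test_input_size_must_be_multiple_of_32():
    with pytest.raises(ValueError, match="32"):
        ModelConfig(input_size=100)


def test_pretrained_requires_weights_path():
    with pytest.raises(ValueError, match="weights_path"):
        ModelConfig(pretrained=True)


def test_same_seed_identical_parameters():
    cfg = ModelConfig(backbone="tiny_fpn", input_size=64)
    a = build_model(cfg, seed=5)
    b = build_model(cfg, seed=5)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        np.testing.assert_array_equal(pa.data, pb.data)


def test_forward_is_deterministic_in_eval(tiny64_model):
    rng = np.random.default_rng(0)
    img = rng.random((64, 64)).astype(np.float32)
    p1 = forward_saliency(tiny64_model, img)
    p2 = forward_saliency(tiny64_model, img)
    for a, b in zip(p1.logits, p2.logits):
        np.testing.assert_array_equal(a, b)


def test_size_mismatch_error_names_sizes(tiny64_model):
    with pytest.raises(ValueError, match="64"):
        forward_saliency(tiny64_model, np.zeros((128, 128)))


def test_constant_filters_give_constant_interior_logits():
    """With every filter constant and normalization off, a constant input
    propagates as a constant in the interior of every map; the expected value
    follows from scalar convolution arithmetic reproduced independently."""
    cfg = ModelConfig(backbone="tiny_fpn", input_size=256, norm="none")
    model = build_model(cfg, seed=0)
    wval, bval = 0.01, 0.005
    for name, p in model.named_parameters():
        p.data = np.full_like(p.data, wval if p.data.ndim == 4 else bval)
    v = 0.3
    pyr = forward_saliency(model, np.full((256, 256), v, dtype=np.float32))

    def conv_scalar(val, cin, k):
        return max(0.0, val * cin * k * k * wval + bval)  # conv + relu

    def head_scalar(val, cin):
        return val * cin * wval + bval  # 1x1 head, no relu

    s0 = conv_scalar(v, 1, 3)
    s1 = conv_scalar(s0, 6, 3)
    enc = []
    val, cins, couts = s1, [12, 16, 20, 24], [16, 20, 24, 32]
    for cin in cins:
        val = conv_scalar(val, cin, 3)
        enc.append(val)
    lat = [e * c * wval + bval for e, c in zip(enc, couts)]  # 1x1 laterals
    fused = [None] * 4
    fused[3] = lat[3]
    for i in (2, 1, 0):
        fused[i] = lat[i] + fused[i + 1]
    width = cfg.fpn_width()
    for out_idx, i in enumerate((3, 2, 1, 0)):
        smooth = conv_scalar(fused[i], width, 3)
        expected = head_scalar(smooth, width)
        size = pyr.logits[out_idx].shape[0]
        c = size // 2
        center = pyr.logits[out_idx][c - 1 : c + 1, c - 1 : c + 1]
        np.testing.assert_allclose(center, expected, rtol=1e-4)


def test_translation_covariance_on_delta_input():
    """Shifting the input by one coarsest-level stride shifts interior
    responses by one pixel per level-stride."""
    cfg = ModelConfig(backbone="tiny_fpn", input_size=256, norm="none")
    model = build_model(cfg, seed=3)
    img = np.zeros((256, 256), dtype=np.float32)
    img[120, 104] = 1.0
    shifted = np.zeros_like(img)
    shifted[120, 104 + 32] = 1.0
    p0 = forward_saliency(model, img)
    p1 = forward_saliency(model, shifted)
    for lv0, lv1, size in zip(p0.logits, p1.logits, p0.level_sizes):
        step = 32 * size // 256
        margin = size // 4
        a = lv0[margin:-margin, margin : -margin - step]
        b = lv1[margin:-margin, margin + step : -margin]
        np.testing.assert_allclose(a, b, atol=1e-4)


def test_image_probability_closed_forms():
    assert image_probability(np.zeros((4, 4))) == pytest.approx(0.5)
    assert image_probability(np.full((2, 2), 50.0)) == pytest.approx(1.0, abs=1e-9)
    m = np.array([[-1.0, 0.0], [2.0, 0.0]])
    assert image_probability(m) == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-12)
    with pytest.raises(ValueError):
        image_probability(np.zeros((0,)))


def test_image_probability_respects_output_level():
    pyr = SaliencyPyramid(logits=[np.full((2, 2), -1.0), np.full((4, 4), 3.0)])
    assert image_probability(pyr, "coarsest") == pytest.approx(1 / (1 + np.e))
    assert image_probability(pyr, "finest") == pytest.approx(1 / (1 + np.exp(-3.0)))


def test_checkpoint_roundtrip_and_config_mismatch(tmp_path, tiny64_model):
    path = tmp_path / "model.npz"
    save_checkpoint(path, tiny64_model)
    loaded = load_checkpoint(path)
    img = np.linspace(0, 1, 64 * 64, dtype=np.float32).reshape(64, 64)
    np.testing.assert_array_equal(
        forward_saliency(loaded, img).logits[0], forward_saliency(tiny64_model, img).logits[0]
    )
    with pytest.raises(ValueError, match="config"):
        load_checkpoint(path, config=ModelConfig(backbone="tiny_fpn", input_size=128))
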