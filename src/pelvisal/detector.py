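"""Encoder + top-down pyramid network producing multiscale saliency logits.

The contract: a square grayscale image of side ``input_size`` (divisible by
32) maps to K=4 logit grids of sides ``input_size/32 .. input_size/4``,
ordered coarse to fine.  Two backbones are provided:

* ``densenet169_fpn`` — a DenseNet-BC-style encoder (dense blocks with
  channel concatenation, 1x1 transition convolutions and 2x downsampling)
  feeding a 256-channel feature-pyramid top-down path.  The block depths and
  growth rate are compact so a full-resolution CPU forward pass is cheap;
  they are configurable for larger runs.
* ``tiny_fpn`` — a narrow plain-convolution encoder for desk-scale training
  experiments.

Both share the same top-down design: 1x1 lateral projections, nearest-
neighbour upsampling with additive fusion, a 3x3 smoothing convolution per
level and a 1x1 head emitting one logit channel per level.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .records import ImageRecord

__all__ = [
    "ModelConfig",
    "SaliencyPyramid",
    "DetectorModel",
    "build_model",
    "forward_saliency",
    "image_probability",
    "save_checkpoint",
    "load_checkpoint",
]

_BACKBONES = ("densenet169_fpn", "tiny_fpn")


@dataclass
class ModelConfig:
    """Architecture configuration.

    ``output_level`` selects the level whose map is treated as "the" output
    heatmap for image-level scoring and ensemble fusion: ``"coarsest"``
    (default, the input/32 grid) or ``"finest"`` (input/4).
    """

    backbone: str = "densenet169_fpn"
    input_size: int = 1024
    pyramid_levels: int = 4
    pretrained: bool = False
    weights_path: Optional[str] = None
    fpn_channels: Optional[int] = None
    output_level: str = "coarsest"
    norm: str = "instance"  # "instance" | "none"; applied after conv, before relu
    # densenet-style encoder shape (ignored by tiny_fpn)
    growth_rate: int = 8
    block_layers: Sequence[int] = (2, 4, 4, 4)

    def __post_init__(self):
        if self.backbone not in _BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; expected one of {_BACKBONES}"
            )
        if self.input_size % 32 != 0 or self.input_size < 32:
            raise ValueError("input_size must be a positive multiple of 32")
        if self.pyramid_levels != 4:
            raise ValueError("only 4 pyramid levels are supported")
        if self.output_level not in ("coarsest", "finest"):
            raise ValueError("output_level must be 'coarsest' or 'finest'")
        if self.norm not in ("instance", "none"):
            raise ValueError("norm must be 'instance' or 'none'")
        if self.pretrained and not self.weights_path:
            raise ValueError(
                "pretrained=True requires weights_path (no weights are bundled)"
            )

    @property
    def level_sizes(self):
        """Level side lengths, coarse to fine (input/32 .. input/4)."""
        return tuple(self.input_size // s for s in (32, 16, 8, 4))

    def fpn_width(self):
        if self.fpn_channels is not None:
            return self.fpn_channels
        return 256 if self.backbone == "densenet169_fpn" else 16


@dataclass
class SaliencyPyramid:
    """Real-valued logit maps P_1..P_K, coarse to fine."""

    logits: List[np.ndarray]

    @property
    def level_sizes(self):
        return tuple(m.shape[-1] for m in self.logits)

    def output_map(self, output_level="coarsest"):
        return self.logits[0] if output_level == "coarsest" else self.logits[-1]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


class _Conv:
    """A convolution's parameters plus its application."""

    def __init__(self, rng, cin, cout, k, stride=1, bias_init=0.0, name=""):
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = nn.parameter(w)
        self.b = nn.parameter(np.full(cout, bias_init, dtype=np.float32))
        self.stride = stride
        self.name = name

    def __call__(self, x):
        return nn.conv2d(x, self.w, self.b, stride=self.stride)

    def params(self):
        return [(self.name + ".w", self.w), (self.name + ".b", self.b)]


class DetectorModel:
    """A built detector: parameters plus the forward computation."""

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(seed)
        self._convs: List[_Conv] = []
        if config.backbone == "tiny_fpn":
            self._build_tiny(rng)
        else:
            self._build_dense(rng)
        if config.weights_path:
            self.load_parameters(config.weights_path)

    # -- construction -----------------------------------------------------
    def _conv(self, rng, cin, cout, k, stride=1, bias_init=0.0, name=""):
        c = _Conv(rng, cin, cout, k, stride=stride, bias_init=bias_init, name=name)
        self._convs.append(c)
        return c

    def _build_fpn_head(self, rng, enc_channels):
        width = self.config.fpn_width()
        self.laterals = [
            self._conv(rng, c, width, 1, name=f"lat{i}") for i, c in enumerate(enc_channels)
        ]
        self.smooths = [
            self._conv(rng, width, width, 3, name=f"smooth{i}") for i in range(4)
        ]
        # background-prior head bias: most pixels are negative
        self.heads = [
            self._conv(rng, width, 1, 1, bias_init=-2.0, name=f"head{i}") for i in range(4)
        ]

    def _build_tiny(self, rng):
        self.stem = [
            self._conv(rng, 1, 6, 3, stride=2, name="stem0"),
            self._conv(rng, 6, 12, 3, stride=2, name="stem1"),
        ]
        self.enc = [
            self._conv(rng, 12, 16, 3, name="enc0"),          # /4
            self._conv(rng, 16, 20, 3, stride=2, name="enc1"),  # /8
            self._conv(rng, 20, 24, 3, stride=2, name="enc2"),  # /16
            self._conv(rng, 24, 32, 3, stride=2, name="enc3"),  # /32
        ]
        self._build_fpn_head(rng, [16, 20, 24, 32])

    def _build_dense(self, rng):
        cfg = self.config
        g = cfg.growth_rate
        self.stem = [self._conv(rng, 1, 16, 7, stride=2, name="stem0")]
        self.dense_blocks = []
        self.transitions = []
        enc_channels = []
        c = 16
        for bi, nlayers in enumerate(cfg.block_layers):
            block = []
            for li in range(nlayers):
                block.append(self._conv(rng, c, g, 3, name=f"block{bi}.{li}"))
                c += g
            self.dense_blocks.append(block)
            enc_channels.append(c)
            if bi < len(cfg.block_layers) - 1:
                ct = c // 2
                self.transitions.append(self._conv(rng, c, ct, 1, name=f"trans{bi}"))
                c = ct
        self._build_fpn_head(rng, enc_channels)

    # -- forward ----------------------------------------------------------
    def _act(self, t):
        if self.config.norm == "instance":
            t = nn.instance_norm(t)
        return nn.relu(t)

    def _encode(self, x):
        if self.config.backbone == "tiny_fpn":
            h = self._act(self.stem[0](x))
            h = self._act(self.stem[1](h))
            feats = []
            for conv in self.enc:
                h = self._act(conv(h))
                feats.append(h)
            return feats  # fine (/4) .. coarse (/32)
        h = self._act(self.stem[0](x))
        h = nn.maxpool2(h)
        feats = []
        for bi, block in enumerate(self.dense_blocks):
            for conv in block:
                h = nn.concat([h, self._act(conv(h))])
            feats.append(h)
            if bi < len(self.transitions):
                h = nn.maxpool2(self._act(self.transitions[bi](h)))
        return feats

    def forward(self, batch):
        """Run the network on a (N, 1, H, W) tensor/array.

        Returns logit tensors ordered coarse to fine.
        """
        x = batch if isinstance(batch, nn.Tensor) else nn.Tensor(batch)
        n, c, h, w = x.shape
        s = self.config.input_size
        if c != 1 or h != s or w != s:
            raise ValueError(f"expected input (N, 1, {s}, {s}), got {x.shape}")
        feats = self._encode(x)  # fine .. coarse
        laterals = [lat(f) for lat, f in zip(self.laterals, feats)]
        # top-down: start at the coarsest, upsample and fuse
        fused = [None] * 4
        fused[3] = laterals[3]
        for i in (2, 1, 0):
            fused[i] = nn.add(laterals[i], nn.upsample2(fused[i + 1]))
        out = []
        for i in (3, 2, 1, 0):  # emit coarse -> fine
            out.append(self.heads[i](self._act(self.smooths[i](fused[i]))))
        return out

    # -- parameters -------------------------------------------------------
    def named_parameters(self):
        out = []
        for c in self._convs:
            out.extend(c.params())
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            if name not in state:
                raise ValueError(f"missing parameter {name!r} in state")
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def load_parameters(self, path):
        with np.load(path) as npz:
            self.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})


def build_model(config: ModelConfig, seed: int) -> DetectorModel:
    """Build a detector with deterministic seed-derived initialization."""
    return DetectorModel(config, seed)


def forward_saliency(model: DetectorModel, image) -> SaliencyPyramid:
    """Evaluate the model on one preprocessed image (pure function)."""
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    if pixels.ndim != 2:
        raise ValueError("forward_saliency expects a single 2-D image")
    s = model.config.input_size
    if pixels.shape != (s, s):
        raise ValueError(f"image size {pixels.shape} does not match input_size {s}")
    out = model.forward(pixels[None, None].astype(np.float32))
    return SaliencyPyramid([t.data[0, 0].astype(np.float64) for t in out])


def image_probability(pyramid_or_map, output_level="coarsest") -> float:
    """Image-level probability: max over pixels of sigmoid(logit).

    Accepts a :class:`SaliencyPyramid` (uses the designated output level) or a
    bare logit map.
    """
    if isinstance(pyramid_or_map, SaliencyPyramid):
        m = pyramid_or_map.output_map(output_level)
    else:
        m = np.asarray(pyramid_or_map)
    if m.size == 0:
        raise ValueError("empty saliency map")
    return float(_sigmoid(m).max())


def save_checkpoint(path, model: DetectorModel):
    """Serialize parameters with the embedded ModelConfig."""
    cfg = dataclasses.asdict(model.config)
    cfg["block_layers"] = list(cfg["block_layers"])
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        **model.state_dict(),
    )


def load_checkpoint(path, config: Optional[ModelConfig] = None) -> DetectorModel:
    """Load a checkpoint; rejects a config mismatch when one is supplied."""
    with np.load(path) as npz:
        stored = json.loads(bytes(npz["__config__"]).decode())
        stored["block_layers"] = tuple(stored["block_layers"])
        stored_cfg = ModelConfig(**stored)
        if config is not None and dataclasses.asdict(config) != dataclasses.asdict(stored_cfg):
            raise ValueError("checkpoint ModelConfig does not match the requested config")
        model = DetectorModel(stored_cfg, seed=0)
        model.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
    return model
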