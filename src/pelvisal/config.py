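"""Run configuration: one YAML mapping covering every pipeline stage.

Every CLI command resolves its configuration (file values overridden by
flags), writes the resolved copy next to its outputs, and logs the seed, so
a run can be reproduced by pointing the same command at the written file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .augment import AugmentationRanges, AugmentationSpec
from .detector import ModelConfig
from .ensemble import TTAConfig
from .masks import MaskConfig
from .phantom import FemurGeometry, PhantomConfig, RingGeometry
from .training import TrainConfig

__all__ = ["RunConfig"]


@dataclass
class EvalOptions:
    n_boot: int = 2000
    cutoff: Optional[float] = None


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    tta: TTAConfig = field(default_factory=TTAConfig.default)
    evaluation: EvalOptions = field(default_factory=EvalOptions)

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, (list, tuple)):
                return [listify(o) for o in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        return listify(dataclasses.asdict(self))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        phantom = d.get("phantom", {})
        if phantom:
            phantom = dict(phantom)
            if "ring_geometry" in phantom:
                rg = dict(phantom["ring_geometry"])
                rg["center"] = tuple(rg["center"])
                phantom["ring_geometry"] = RingGeometry(**rg)
            if "femur_geometry" in phantom:
                fgs = []
                for fg in phantom["femur_geometry"]:
                    fg = dict(fg)
                    fg["head_center"] = tuple(fg["head_center"])
                    fg["shaft_end"] = tuple(fg["shaft_end"])
                    fgs.append(FemurGeometry(**fg))
                phantom["femur_geometry"] = tuple(fgs)
        mask = dict(d.get("mask", {}))
        if "level_sizes" in mask:
            mask["level_sizes"] = tuple(mask["level_sizes"])
        model = dict(d.get("model", {}))
        if "block_layers" in model:
            model["block_layers"] = tuple(model["block_layers"])
        train = dict(d.get("train", {}))
        if "augment" in train:
            aug = dict(train["augment"])
            for k in ("scale", "brightness", "contrast"):
                if k in aug:
                    aug[k] = tuple(aug[k])
            train["augment"] = AugmentationRanges(**aug)
        tta = d.get("tta", {})
        specs = [AugmentationSpec(**s) for s in tta.get("specs", [])] if tta else None
        return cls(
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir", "runs"),
            phantom=PhantomConfig(**phantom) if phantom else PhantomConfig(),
            mask=MaskConfig(**mask) if mask else MaskConfig(),
            model=ModelConfig(**model) if model else ModelConfig(),
            train=TrainConfig(**train) if train else TrainConfig(),
            tta=TTAConfig(specs=specs) if specs else TTAConfig.default(),
            evaluation=EvalOptions(**d.get("evaluation", {})),
        )

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text))
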