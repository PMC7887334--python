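import numpy as np
import pytest

from pelvisal.detector import ModelConfig, build_model
from pelvisal.phantom import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def small_phantom_config():
    return PhantomConfig(image_size=128)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_phantom_config):
    """A 30-image phantom dataset shared by tests that only read it."""
    out = tmp_path_factory.mktemp("dataset")
    return generate_dataset(30, 0.5, small_phantom_config, seed=7, out_dir=out)


@pytest.fixture()
def tiny64_model():
    cfg = ModelConfig(backbone="tiny_fpn", input_size=64, pretrained=False)
    return build_model(cfg, seed=0)


def constant_logit_model(input_size: int, logit: float, output_level="coarsest"):
    """A detector whose every saliency map is identically ``logit``."""
    cfg = ModelConfig(
        backbone="tiny_fpn", input_size=input_size, output_level=output_level
    )
    model = build_model(cfg, seed=0)
    for name, p in model.named_parameters():
        if name.startswith("head"):
            p.data = (
                np.full_like(p.data, logit) if p.data.ndim == 1 else np.zeros_like(p.data)
            )
    return model
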