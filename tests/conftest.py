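import numpy as np
import pytest

from coatseg.model import CoatSegNet, ModelConfig
from coatseg.synthetic import SyntheticSpec, generate_sample
from coatseg.train import AugmentConfig, Trainer, evaluate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight synthetic 64 px tongue images with fixed seed."""
    spec = SyntheticSpec(image_size=64, seed=7)
    return [generate_sample(spec, i) for i in range(8)]


@pytest.fixture(scope="session")
def overfit_run(tiny_dataset):
    """A tiny network trained 200 Adam steps on the eight training images.

    Session-scoped: the trained network backs the trainability, loss-weight
    and attention-localization checks.
    """
    net = CoatSegNet(ModelConfig.tiny(64, seed=1))
    trainer = Trainer(net, seed=1)
    trainer.fit(
        tiny_dataset, steps=200,
        augment=AugmentConfig(enabled=False), batch_size=8,
    )
    report = evaluate(net, tiny_dataset)
    return {"net": net, "trainer": trainer, "report": report,
            "data": tiny_dataset}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
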