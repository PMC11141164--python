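import numpy as np
import pytest

from datransunet import (PhantomSpec, TrainConfig, build_model, make_binary_phantoms,
                         r50_config, tiny_config, train)


@pytest.fixture(scope="session")
def r50_baseline():
    """Full-scale hybrid model with every DA component disabled."""
    return build_model(r50_config(da_encoder=False, da_skips=(False, False, False)),
                       seed=0)


@pytest.fixture(scope="session")
def r50_full():
    """Full-scale hybrid model with encoder DA and all three skip DAs."""
    return build_model(r50_config(), seed=0)


@pytest.fixture(scope="session")
def overfit_phantoms():
    """Eight noisy binary lesion phantoms used by the capacity checks."""
    return make_binary_phantoms(
        PhantomSpec(n_images=8, img_size=64, mode="binary", seed=7))


@pytest.fixture(scope="session")
def overfit_run(overfit_phantoms):
    """Train the tiny model to memorize the 8 phantoms (shared, expensive).

    Training stops as soon as train-set Dice clears 0.96, within the
    200-epoch cap the capacity check allows.
    """
    cfg = TrainConfig(network=tiny_config(n_classes=1), epochs=200,
                      val_fraction=0.0, stop_at_dice=0.96, seed=3)
    model, history = train(cfg, overfit_phantoms)
    return model, history, overfit_phantoms
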