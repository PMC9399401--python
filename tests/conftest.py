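import numpy as np
import pytest

from gaitlift.pose_lifting import LiftingConfig, build_model, train
from gaitlift.synthetic_gait import GaitSimConfig, generate, make_training_set

#: Desk-scale training conditions: a small fit that one CPU handles in about
#: a minute while still recovering the synthetic 2D->3D map accurately.
DESK_LIFTING = dict(hidden=256, blocks=2, dropout=0.0, epochs=200,
                    learning_rate=1e-3, lr_decay=0.99, batch_size=64, seed=0)
DESK_TRAIN_POSES = 2000


@pytest.fixture(scope="session")
def sim_config():
    return GaitSimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_bundle(sim_config):
    """A clean 10 s walking bout at 60 Hz with analytic ground truth."""
    return generate(sim_config)


@pytest.fixture(scope="session")
def noisy_bundle():
    """The same bout observed with 2 px keypoint noise."""
    return generate(GaitSimConfig(seed=7, noise_px=2.0))


@pytest.fixture(scope="session")
def desk_model(sim_config):
    """Lifter trained on 2000 synthetic pose pairs (shared across tests).

    Training inputs carry the same 2 px keypoint noise as the noisy
    observation condition, so the network is fit under the noise it will
    see at inference.
    """
    batch = make_training_set(sim_config, DESK_TRAIN_POSES, seed=11,
                              noise_px=2.0)
    config = LiftingConfig(**DESK_LIFTING)
    model = build_model(config)
    history = train(model, batch, config)
    model.history = history
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
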