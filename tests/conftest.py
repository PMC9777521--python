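import numpy as np
import pytest

from aidunet.archspec import ArchConfig, plan_layers
from aidunet.network import TrainConfig, build_model, train
from aidunet.synthetic_data import FixtureSpec, make_dataset

# Desk-scale end-to-end training condition: AID-U-Net(2, 1) on 64 synthetic
# blob images of 64x64, 10 epochs.  N_f=4 (base 16 filters) and no dropout
# keep the run CPU-friendly while leaving the architecture untouched.
SMOKE_ARCH = ArchConfig(
    direct_depth=2,
    sub_depth=1,
    filter_factor=4,
    dims=2,
    in_channels=3,
    num_classes=2,
    input_extent=(64, 64),
    dropout_rate=0.0,
)
SMOKE_FIXTURE = FixtureSpec(count=64, extent=(64, 64), dims=2, channels=3,
                            rng_seed=7)
SMOKE_TRAIN = TrainConfig(epochs=10, batch_size=8, learning_rate=1e-3,
                          rng_seed=7, loss="generalized_dice",
                          validation_fraction=0.25)


@pytest.fixture(scope="session")
def blob_dataset():
    samples, manifest = make_dataset(SMOKE_FIXTURE)
    return samples, manifest


@pytest.fixture(scope="session")
def trained_smoke(blob_dataset):
    """AID-U-Net(2,1) trained once on the shared blob fixture; reused by the
    end-to-end acceptance check and the training-dynamics properties."""
    samples, _ = blob_dataset
    model = build_model(plan_layers(SMOKE_ARCH), seed=SMOKE_TRAIN.rng_seed)
    model, history = train(model, samples, SMOKE_TRAIN)
    return model, history, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
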