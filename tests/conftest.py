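import numpy as np
import pytest

from seston import binning, classify, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced noise-free synthetic set, 12 images per class."""
    records, manifest = simulate.generate_dataset(12, seed=7, noise_sd=0.0)
    return records, manifest


@pytest.fixture(scope="session")
def small_splits(small_dataset):
    _, manifest = small_dataset
    return binning.split_dataset(manifest, seed=7)


@pytest.fixture(scope="session")
def trained_model(small_dataset, small_splits):
    records, _ = small_dataset
    by_id = {r.image_id: r for r in records}
    train = [by_id[i] for i in small_splits["train"]["image_id"]]
    val = [by_id[i] for i in small_splits["val"]["image_id"]]
    model = classify.train_classifier(
        train,
        small_splits["train"],
        val,
        small_splits["val"],
        config=classify.TrainConfig(seed=7),
    )
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(20240926)
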