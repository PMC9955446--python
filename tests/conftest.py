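"""Shared fixtures.

The expensive end-to-end fixtures (default-scale phantom dataset and a
trained classifier) are session-scoped so behavioural tests share one
training run; small-scale fixtures exist for the fast unit tests.
"""

import numpy as np
import pytest

import dropweak as dw
from dropweak.rng import substream

SESSION_SEED = 202


def small_spec(n: int = 120, seed: int = 123) -> dw.SyntheticSpec:
    """A 32x32 phantom spec for fast tests (diameters scaled to fit)."""
    return dw.SyntheticSpec(
        n_images=n,
        image_size=32,
        benign_diameter_range=(3.0, 7.0),
        malignant_diameter_range=(10.0, 18.0),
        seed=seed,
    )


def small_arch(**kw) -> dw.ArchitectureConfig:
    return dw.ArchitectureConfig(input_size=(32, 32), channels=(6, 12), **kw)


@pytest.fixture(scope="session")
def small_dataset() -> dw.SyntheticDataset:
    return dw.generate_dataset(small_spec())


@pytest.fixture(scope="session")
def trained_setup():
    """Default-scale phantom (n=2000, 64x64) plus a trained classifier.

    Trained once per session: 24 epochs of Adam at 1.5e-3, batch 16, on
    the 80/10/10 split — the desk-scale study conditions.
    """
    spec = dw.SyntheticSpec(n_images=2000, seed=SESSION_SEED)
    dataset = dw.generate_dataset(spec)
    ads = dw.ArrayDataset(dataset.images, dataset.labels)
    model = dw.build_model(dw.ArchitectureConfig(), substream(SESSION_SEED, "init"))
    tcfg = dw.TrainConfig(seed=SESSION_SEED, learning_rate=1.5e-3, epochs=24)
    dw.train(model, ads, tcfg)
    idx_test = ads.splits["test"]
    return {
        "spec": spec,
        "dataset": dataset,
        "array_dataset": ads,
        "model": model,
        "train_config": tcfg,
        "test_idx": idx_test,
        "x_test": dataset.images[idx_test],
        "y_test": dataset.labels[idx_test],
    }
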