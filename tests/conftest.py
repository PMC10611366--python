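"""Shared fixtures.

The heavy session fixtures (the 200-phantom dataset and the two trained
networks) are built once and reused by the classifier, regressor, pipeline
and acceptance tests; everything that only needs a handful of phantoms
builds its own small set.
"""

from __future__ import annotations

import numpy as np
import pytest

from mandicort import generate_dataset, split_dataset
from mandicort.phantom import PhantomSpec
from mandicort.pipeline import train_models

#: conditions of the scaled-down training experiment: 200 noise-free
#: phantoms with 64x64 slices, 70:30 split
EXPERIMENT_SEED = 20230922


@pytest.fixture(scope="session")
def phantom_dataset():
    base = PhantomSpec(noise_sd=0.0)
    return generate_dataset(200, seed=EXPERIMENT_SEED, base_spec=base)


@pytest.fixture(scope="session")
def phantom_split(phantom_dataset):
    return split_dataset(phantom_dataset, 0.7, seed=EXPERIMENT_SEED + 1)


@pytest.fixture(scope="session")
def trained_models(phantom_split):
    """Both stage networks trained once on the 70:30 split."""
    train_items, val_items = phantom_split
    model1, c_metrics, model2, r_hist = train_models(
        train_items, val_items, seed=EXPERIMENT_SEED)
    return {
        "stage1": model1,
        "stage1_metrics": c_metrics,
        "stage2": model2,
        "stage2_history": r_hist,
        "train_items": train_items,
        "val_items": val_items,
    }


@pytest.fixture()
def small_phantoms():
    """Five quick noise-free phantoms for structural tests."""
    return generate_dataset(5, seed=11, base_spec=PhantomSpec(noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
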