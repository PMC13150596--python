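"""Shared fixtures: small synthetic datasets and prepared train/test splits."""

from __future__ import annotations

import numpy as np
import pytest

import chemodisc as cd


@pytest.fixture(scope="session")
def uv_dataset():
    """Default UV-vis-like dataset (99 replicate rows) plus ground truth."""
    return cd.generate_dataset(cd.uv_default_config(seed=7))


@pytest.fixture(scope="session")
def ftir_dataset():
    return cd.generate_dataset(cd.ftir_default_config(seed=7))


def prepare_supervised(ds):
    """Replicate-average, preprocess (no centering), split, train-center.

    Returns (preprocessed dataset, split, X_centered, y).
    """
    avg = cd.average_replicates(ds)
    pre, _ = cd.preprocess_dataset(avg, cd.PreprocessConfig(center="none"))
    split = cd.stratified_split(pre)
    means = pre.intensities[split.train_indices].mean(axis=0)
    X = pre.intensities - means
    return pre, split, X, pre.class_vector()


@pytest.fixture(scope="session")
def uv_supervised(uv_dataset):
    ds, gt = uv_dataset
    pre, split, X, y = prepare_supervised(ds)
    return {"pre": pre, "split": split, "X": X, "y": y, "gt": gt}


@pytest.fixture(scope="session")
def ftir_supervised(ftir_dataset):
    ds, gt = ftir_dataset
    pre, split, X, y = prepare_supervised(ds)
    return {"pre": pre, "split": split, "X": X, "y": y, "gt": gt}


@pytest.fixture
def tiny_dataset():
    """4 rows = 2 samples x 2 replicates on a 5-point axis."""
    return cd.SpectralDataset(
        axis=[240.0, 241.0, 242.0, 243.0, 244.0],
        intensities=np.arange(20, dtype=float).reshape(4, 5),
        sample_ids=["LU01", "LU01", "MI01", "MI01"],
        replicate_ids=[1, 2, 1, 2],
        classes=["LU", "LU", "MI", "MI"],
    )


@pytest.fixture
def separable_2class():
    """Two well-separated 2-D Gaussian clouds, 12 rows per class."""
    rng = np.random.default_rng(42)
    a = rng.normal([0.0, 0.0], 0.3, size=(12, 2))
    b = rng.normal([3.0, 2.0], 0.3, size=(12, 2))
    X = np.vstack([a, b])
    y = np.array(["A"] * 12 + ["B"] * 12)
    return X, y
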