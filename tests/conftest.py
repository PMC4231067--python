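"""Shared fixtures: seeded synthetic data and derived LPC feature matrices."""

from __future__ import annotations

import numpy as np
import pytest

from pcgclassify import (
    extract_features,
    generate_dataset,
    segment_heart_tones,
)
from pcgclassify.pipeline import recording_features
from pcgclassify.signals import SegmentationConfig


def features_of_dataset(dataset, order: int = 24):
    """One LPC vector per recording (enclosing-span window), plus labels."""
    seg_cfg = SegmentationConfig()
    X, y = [], []
    for rec, label in dataset.samples:
        X.append(recording_features(rec, seg_cfg, order))
        y.append(label)
    return np.asarray(X), y


@pytest.fixture(scope="session")
def dataset72():
    """The study-scale dataset: 6 realizations of each of the 12 classes."""
    return generate_dataset(6, 4000.0, seed=42)


@pytest.fixture(scope="session")
def features72(dataset72):
    return features_of_dataset(dataset72)


@pytest.fixture(scope="session")
def small_feature_set():
    """24 recordings (2 per class) for fast classifier tests."""
    ds = generate_dataset(2, 4000.0, seed=7)
    return features_of_dataset(ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
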