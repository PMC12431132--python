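"""Shared fixtures: a small synthetic scalogram dataset and a trained CNN.

Session-scoped because simulation + CWT rendering dominate the suite's
runtime; tests must not mutate these objects in place.
"""

from __future__ import annotations

import numpy as np
import pytest

from drowsyeeg import SimConfig, balance_by_augmentation, build_scalogram_dataset
from drowsyeeg.models import ConvNetClassifier


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A 6-subject cohort with the default spectral contrast."""
    return SimConfig(n_subjects=6, seed=7)


@pytest.fixture(scope="session")
def scalogram_dataset(small_sim_config):
    """~200 labeled scalograms (with source segments) from 6 subjects."""
    ds = build_scalogram_dataset(small_sim_config, windows_per_session=6)
    return balance_by_augmentation(ds, seed=7)


@pytest.fixture(scope="session")
def trained_cnn(scalogram_dataset) -> ConvNetClassifier:
    """A three-block CNN trained on the shared dataset."""
    clf = ConvNetClassifier(depth=3, epochs=30, random_state=7)
    clf.fit(scalogram_dataset.images, scalogram_dataset.labels)
    return clf


@pytest.fixture(scope="session")
def cnn_features(trained_cnn, scalogram_dataset) -> np.ndarray:
    return trained_cnn.transform(scalogram_dataset.images)
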