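"""Shared fixtures: small synthetic channels featurized once per session."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from twincross import benchmarks, learning

logging.getLogger("twincross").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def high_contrast_ds():
    """Separable 150/150 channel, fixed seed."""
    return benchmarks.separable_channel(150, 150, seed=11)


@pytest.fixture(scope="session")
def high_contrast_feats(high_contrast_ds):
    return learning.TwinFeatures.from_patches(high_contrast_ds.patches)


@pytest.fixture(scope="session")
def tiny_ds():
    """20/20 channel for cheap structural tests."""
    return benchmarks.separable_channel(20, 20, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
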