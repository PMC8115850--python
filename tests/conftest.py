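"""Shared fixtures: tiny phantom cohorts and desk-scale model configs."""

from __future__ import annotations

import numpy as np
import pytest

from osteoage import pipeline
from osteoage.phantom import PhantomParams


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12 noise-free-geometry phantoms preprocessed to desk-scale voxels."""
    params = PhantomParams(n_subjects=12, seed=42)
    samples, truth = pipeline.phantom_dataset(params, downsample=pipeline.DESK_DOWNSAMPLE)
    return samples, truth


@pytest.fixture()
def tiny_net_config():
    """Smallest sensible femur-only network for fast structural tests."""
    cfg = pipeline.desk_network_config(seed=5)
    cfg.scale = 0.0625
    return cfg


@pytest.fixture()
def tiny_train_config():
    cfg = pipeline.desk_train_config(seed=5, epochs=3)
    return cfg
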