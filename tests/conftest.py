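"""Shared fixtures: session-scoped synthetic models at test-friendly sizes."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from retmap.synthetic import SyntheticConfig, make_dataset, make_synthetic_model


@pytest.fixture(scope="session")
def small_cfg():
    """Coarse study conditions for fast unit tests (same layout, fewer
    vertices than the default)."""
    return SyntheticConfig(resolution=0.2, seed=0)


@pytest.fixture(scope="session")
def small_model(small_cfg):
    return make_synthetic_model(small_cfg)


@pytest.fixture(scope="session")
def default_model():
    """The default-resolution fixture model (shared; built once)."""
    return make_synthetic_model()


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_model):
    return make_dataset(small_cfg, n_scans=2, model=small_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
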