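"""Shared fixtures: small phantoms rendered once per session."""

import numpy as np
import pytest
from hypothesis import settings

from octdent import SystemSpec

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from octdent.phantom import PhantomConfig, make_phantom, preset


@pytest.fixture(scope="session")
def spec() -> SystemSpec:
    return SystemSpec()


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Reduced grid for fast unit tests; full-size runs live in acceptance tests."""
    return PhantomConfig(n_bscans=4, n_ascans=256, n_depth=300, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return make_phantom(small_config)


@pytest.fixture(scope="session")
def noise_free_phantom():
    cfg = PhantomConfig(
        n_bscans=2, n_ascans=256, n_depth=300, speckle=False, noise_floor=0.0, seed=5
    )
    return cfg, *make_phantom(cfg)


@pytest.fixture(scope="session")
def calculus_phantom():
    cfg = preset("calculus", seed=3, calculus_thickness_um=30.0, n_bscans=4, n_ascans=256)
    return cfg, *make_phantom(cfg)
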