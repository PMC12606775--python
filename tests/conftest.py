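"""Shared fixtures: small synthetic sessions, cached per test session."""

from __future__ import annotations

import numpy as np
import pytest

from gaitspm import SessionConfig, generate_session
from gaitspm.synthetic import NOISE_FREE, NoiseSpec


@pytest.fixture(scope="session")
def short_config() -> SessionConfig:
    """Replication conditions with 20 s trials (~15-18 strides each)."""
    return SessionConfig(trial_duration=20.0)


@pytest.fixture(scope="session")
def noise_free_session(short_config):
    return generate_session(short_config, seed=3, noise=NOISE_FREE)


@pytest.fixture(scope="session")
def noisy_session(short_config):
    return generate_session(short_config, seed=3, noise=NoiseSpec())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
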