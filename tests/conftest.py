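import numpy as np
import pytest

from holoflex import EnsembleConfig, generate_ensemble, measure_ensemble


@pytest.fixture(scope="session")
def default_ensemble():
    """1,000-particle separation-explicit ensemble at the calibrated
    defaults (the dataset the geometry pipeline is validated on)."""
    cfg = EnsembleConfig(n_particles=1000, seed=42)
    return cfg, generate_ensemble(cfg)


@pytest.fixture(scope="session")
def default_measurements(default_ensemble):
    _, particles = default_ensemble
    return measure_ensemble(particles)


@pytest.fixture(scope="session")
def dodecamer_ensemble():
    """4,000 12-mers for pair-count categorical recovery."""
    cfg = EnsembleConfig(n_particles=4000, seed=7, p_tetradecamer=0.0)
    return cfg, generate_ensemble(cfg)


@pytest.fixture(scope="session")
def angular_ensemble():
    cfg = EnsembleConfig(n_particles=600, seed=3, mode="angular")
    return cfg, generate_ensemble(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
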