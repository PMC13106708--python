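import numpy as np
import pytest

from diatom_sync.lightfield import (
    ActionSpectrum,
    constant_field,
    default_action_spectrum,
    pulsed_field,
)
from diatom_sync.population_sim import KO, WT, SimConfig, simulate


@pytest.fixture(scope="session")
def action():
    return default_action_spectrum()


@pytest.fixture(scope="session")
def simple_action():
    """Idealized cross-sections with no band overlap (activation at 660 = 0)."""
    return ActionSpectrum(
        {430.0: 1.0, 530.0: 0.0, 660.0: 0.0, 780.0: 1.0},
        {430.0: 0.0, 530.0: 0.0, 660.0: 1.0, 780.0: 0.0},
    )


def small_config(**overrides):
    """Reduced-scale configuration for fast unit tests."""
    kwargs = dict(n_cells=100, duration_s=1200.0, seed=7)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def coherent_trajectory(action):
    """Small synchronized WT population under constant blue light."""
    cfg = small_config(genotype=WT, duration_s=1800.0)
    return simulate(cfg, constant_field(430.0, 8.0, cfg.duration_s), action)


@pytest.fixture(scope="session")
def incoherent_trajectory(action):
    """Small knockout population (no gating) under the same light."""
    cfg = small_config(genotype=KO, duration_s=1800.0)
    return simulate(cfg, constant_field(430.0, 8.0, cfg.duration_s), action)


@pytest.fixture(scope="session")
def forced_trajectory(action):
    """Small WT population entrained by pulsed red light."""
    cfg = small_config(genotype=WT, duration_s=1800.0)
    return simulate(cfg, pulsed_field(660.0, 8.0, cfg.duration_s), action)
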