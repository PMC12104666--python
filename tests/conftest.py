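import numpy as np
import pandas as pd
import pytest

from natdisp import SimConfig, simulate_study


def perfect_detection() -> dict:
    return {"chick_dna": 1.0, "adult_feather": 1.0, "ring_resight": 1.0,
            "gps_tag": 0.0, "gps_reliability": 1.0, "floater_resight": 0.0}


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced study: fewer territories and years, same structure."""
    return SimConfig(region_extent=(120.0, 120.0), n_years=8,
                     initial_territories=40, seed=11)


@pytest.fixture(scope="session")
def perfect_study():
    """Perfect detection, zero dropout: every event observable."""
    cfg = SimConfig(region_extent=(120.0, 120.0), n_years=8,
                    initial_territories=40, dropout_rate=0.0,
                    detection=perfect_detection(), seed=5)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """A full-size study under the default (imperfect) observation model."""
    return simulate_study(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
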