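import warnings

import numpy as np
import pytest

from domemap.synth import SimConfig


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture
def small_suspension_config():
    cfg = SimConfig(seed=11)
    cfg.suspension.n_events_per_sample = 2500
    return cfg


@pytest.fixture(scope="session")
def imc_rois():
    """Two simulated ROIs with ground truth, shared across tests."""
    from domemap.synth import simulate_imc_rois

    cfg = SimConfig(seed=7)
    cells, zones, truth = simulate_imc_rois(cfg, n_rois=2)
    return cells, zones, truth.set_index("cell_id")


@pytest.fixture(scope="session")
def spot_sample():
    from domemap.synth import simulate_spot_sample

    cfg = SimConfig(seed=7)
    return simulate_spot_sample(cfg)
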