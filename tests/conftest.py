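import numpy as np
import pytest

from yieldvi.synthetic import SimConfig, simulate_experiment
from yieldvi.vegindex import compute_all


@pytest.fixture(scope="session")
def trial():
    """One default synthetic water-stress trial (120 plots)."""
    return simulate_experiment(SimConfig(seed=42))


@pytest.fixture(scope="session")
def vitable(trial):
    return compute_all(trial.plots)


@pytest.fixture(scope="session")
def yields(trial):
    return trial.plots["yield_t_ha"].to_numpy(dtype=float)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
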