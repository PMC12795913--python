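import numpy as np
import pytest

from vptsim import (
    DeviceModel,
    LatencyModel,
    identity_db_device,
    single_condition_observer,
)
from vptsim.observer import DETERMINISTIC_STEP


@pytest.fixture(scope="session")
def identity_device():
    """linear_db device where dB equals the command percent (1..100)."""
    return identity_db_device()


@pytest.fixture(scope="session")
def bench_device():
    """linear_db device spanning 60-159 dB: 1 dB per command percent."""
    return DeviceModel.linear_db(60.0, 159.0)


@pytest.fixture
def step_observer():
    """Factory for deterministic step observers (detect iff level >= mu)."""

    def make(mu_db: float = 12.0):
        return single_condition_observer(mu_db, sigma_db=1.0, form=DETERMINISTIC_STEP)

    return make


@pytest.fixture
def gauss_observer():
    """Factory for cumulative-Gaussian observers on the benchmark scale."""

    def make(mu_db: float = 110.0, sigma_db: float = 4.0, seed=0, latency=None):
        return single_condition_observer(
            mu_db, sigma_db, seed=seed, latency=latency or LatencyModel(kind="zero"))

    return make


@pytest.fixture(scope="session")
def recovery_result():
    """Shared 200-replicate mixed-model parameter recovery (heavy)."""
    from vptsim.reproduce import lmm_parameter_recovery

    return lmm_parameter_recovery(n_replicates=200, seed=20260928)


def spawn_seeds(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)
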