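import numpy as np
import pytest

from mearf import PhaseProtocol, ScenarioConfig, generate_scenario
from mearf.pipeline import analyze_culture


@pytest.fixture(scope="session")
def protocol():
    return PhaseProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Desk-scale five-phase protocol (2 min phases) for fast tests."""
    return PhaseProtocol(durations_s=(120.0,) * 5)


@pytest.fixture(scope="session")
def sham_dataset(protocol):
    return generate_scenario(ScenarioConfig(), protocol, seed=11)


@pytest.fixture(scope="session")
def suppressed_dataset(protocol):
    cfg = ScenarioConfig.exposure_like(0.5)
    return generate_scenario(cfg, protocol, seed=12)


@pytest.fixture(scope="session")
def analyzed_sham(sham_dataset, protocol):
    bursts, table, network = analyze_culture(sham_dataset.spike_trains, protocol)
    return sham_dataset, bursts, table, network


def pytest_configure(config):
    np.seterr(all="warn")
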