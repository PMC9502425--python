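import pytest

import sios2 as s


@pytest.fixture(scope="session")
def geometry():
    return s.zse27_geometry()


@pytest.fixture(scope="session")
def pvpva():
    return s.PVPVA


@pytest.fixture(scope="session")
def all_materials():
    return [s.PVPVA, s.SOL, s.BBMA]


@pytest.fixture
def noiseless_scenario():
    """PVPVA-like ground truth, 8-speed ramp, no measurement noise."""
    return s.noiseless(s.reference_scenario(seed=0))


@pytest.fixture
def noiseless_campaign(noiseless_scenario):
    return noiseless_scenario, s.simulate_autogenic_campaign(noiseless_scenario)
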