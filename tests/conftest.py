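import numpy as np
import pytest

import rhizoflux as rf


@pytest.fixture(scope="session")
def fig5_clean():
    """Noise-free layered O2 scenario (surface 55 uM, anoxic gap, 80 uM root)."""
    return rf.solve_steady_state(rf.scenario_spec("fig5_o2"))


@pytest.fixture(scope="session")
def two_zone_clean():
    """Noise-free consumption-then-production O2 profile."""
    return rf.solve_steady_state(rf.scenario_spec("two_zone"))


@pytest.fixture()
def linear_o2():
    """Exactly linear O2 profile, 0.1 -> 0 umol/cm3 over 0.1 cm."""
    z = np.linspace(0.0, 0.1, 21)
    return rf.MicroProfile(rf.Analyte.O2, z, 0.1 - z)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120323)
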