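import numpy as np
import pytest

from pcgkit import Recording, SimConfig, simulate_pcg

#: generator settings shared by the desk-scale test datasets
TEST_SIM = dict(duration_range=(5.0, 15.0))


@pytest.fixture(scope="session")
def pcg_small():
    """10 labelled PCG recordings with annotations (mixed classes)."""
    return simulate_pcg(SimConfig(seed=1, **TEST_SIM), 10)


@pytest.fixture(scope="session")
def pcg_high_snr_200():
    """200 recordings with a strong (+20 dB) systolic murmur contrast."""
    return simulate_pcg(SimConfig(seed=7, murmur_snr_db=20.0, **TEST_SIM), 200)


@pytest.fixture()
def tone():
    """2 s unit-amplitude 100 Hz tone recording at 1 kHz."""
    t = np.arange(2000) / 1000.0
    return Recording("tone100", np.cos(2 * np.pi * 100 * t), 1000.0, "normal")
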