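import numpy as np
import pytest

import deerloop as dl
from deerloop.instrument_sim import GroundTruthSample


@pytest.fixture(scope="session")
def resonator1() -> dl.ResonatorProfile:
    """High-B1 loop-gap resonator fixture (Q = 70, nu1max = 70 MHz)."""
    return dl.ResonatorProfile(omega_c=34.0, q_factor=70.0, nu1_max=70.0)


@pytest.fixture(scope="session")
def ground_truth() -> GroundTruthSample:
    return GroundTruthSample()


@pytest.fixture(scope="session")
def nitroxide_spectrum(ground_truth) -> dl.Spectrum:
    """Noise-free Q-band nitroxide absorption line on a 2 MHz grid."""
    offs = np.arange(-400.0, 401.0, 2.0)
    amp = ground_truth.spectral_amplitude(offs)
    return dl.Spectrum(offs, amp / amp.max(), gamma_eff=28.1, carrier=34.0)


@pytest.fixture(scope="session")
def sample_suite():
    return dl.make_fixture_suite()
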