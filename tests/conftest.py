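import numpy as np
import pytest

from thinfil import Condition, KineticParams, OpticsParams


@pytest.fixture
def kinetics():
    """Default actomyosin cycle rates (kb0=0.00055, kD=350, kT=2)."""
    return KineticParams()


@pytest.fixture
def optics():
    """Default optics: e=450/s, PSF 160 nm (2 px of 80 nm), sigma_F=0.22."""
    return OpticsParams()


@pytest.fixture
def noise_free_optics():
    return OpticsParams(sigma_F=0.0)


def make_condition(**kw) -> Condition:
    """Condition with study-typical defaults, overridable per test."""
    base = dict(myo_nM=15.0, atp_uM=0.5, epsilon=0.06, frame_rate_hz=10.0,
                n_frames=10, sigma_N=0.0)
    base.update(kw)
    return Condition(**base)


def seeds_from(master: int, n: int):
    return np.random.SeedSequence(master).spawn(n)
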