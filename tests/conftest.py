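import numpy as np
import pytest

from uteqmt.signal_models import TwoPoolParams, default_protocol
from uteqmt import synthetic_data as sd


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture
def typical_params():
    """A representative OCJ-like two-pool parameter set."""
    return TwoPoolParams(f=0.15, r_exch=60.0, t2mm_s=10e-6, t1w_s=1.2, t2w_s=0.030, m0=100.0)


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced layered phantom that keeps volume fits fast."""
    spec = sd.PhantomSpec(shape=(16, 16, 4), n_bg_top=2, n_superficial=4, n_ocj=3, n_bone=4)
    return sd.make_phantom(spec)


def two_pool_steady_state_oracle(params, omega1, offset_hz, g, r1_bound=1.0):
    """Independent Bloch–McConnell steady-state solver (numerical 2x2 solve).

    Longitudinal rate equations under CW saturation, with bound-pool
    saturation rate pi*w1^2*g and the water Lorentzian direct-saturation
    rate w1^2/((2*pi*offset)^2*T2w); solved with numpy.linalg.solve rather
    than the closed-form expression used by the implementation.
    """
    f = params.f
    m0a, m0b = 1.0 - f, f
    ra, rb = 1.0 / params.t1w_s, r1_bound
    kab, kba = params.r_exch * m0b, params.r_exch * m0a
    wb = np.pi * omega1**2 * g
    wa = (omega1 / (2 * np.pi * offset_hz)) ** 2 / params.t2w_s
    A = np.array([[ra + kab + wa, -kba], [-kab, rb + kba + wb]])
    rhs = np.array([ra * m0a, rb * m0b])
    mza, _ = np.linalg.solve(A, rhs)
    return params.m0 * mza / m0a
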