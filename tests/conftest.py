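import numpy as np
import pytest

from tcsgain import SystemParams


@pytest.fixture
def default_params():
    return SystemParams()


@pytest.fixture
def bistable_params():
    """Parameter set known to carry three fixed points at high capacity."""
    return SystemParams(
        f=5.0, h=2.0, D_star=4.0, K_star=0.5, R_b_star=2.5,
        Ct_star=3.0, Cp_star=50.0,
    )


@pytest.fixture
def monostable_params(bistable_params):
    """Same as bistable_params but with weak decoy affinity (K*=2)."""
    return bistable_params.replace(K_star=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def loglog_derivative(fn, x, eps=1e-7):
    """Central-difference d log fn / d log x — the oracle for all gain checks."""
    lo, hi = x * np.exp(-eps), x * np.exp(eps)
    return (np.log(fn(hi)) - np.log(fn(lo))) / (2.0 * eps)
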