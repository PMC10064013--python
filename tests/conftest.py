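import numpy as np
import pytest

from splitroot import GrowthParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def det_params():
    """A fully deterministic two-order parameter set (all sds zero, no
    tropism noise): primaries of 10 cm growing 1 cm/day with laterals
    every 2 cm between 1-cm unbranched zones at base and tip."""
    return {
        0: GrowthParams(branching_number=0, maxB=1, r_mean=1.0, lmax_mean=10.0,
                        la=1.0, lb=1.0, ln_mean=2.0, theta_mean=0.0,
                        max_order=1),
        1: GrowthParams(branching_number=1, r_mean=0.5, lmax_mean=1.0,
                        ln_mean=1.0, theta_mean=60.0, max_order=1),
    }


@pytest.fixture
def noisy_params():
    """A stochastic two-order parameter set exercising every noise source."""
    return {
        0: GrowthParams(branching_number=0, maxB=3, r_mean=1.0, r_sd=0.1,
                        lmax_mean=8.0, lmax_sd=1.0, la=0.5, lb=0.5,
                        ln_mean=0.5, ln_sd=0.05, theta_mean=10.0, theta_sd=5.0,
                        tropism_sigma=10.0, max_order=1),
        1: GrowthParams(branching_number=1, r_mean=0.4, r_sd=0.05,
                        lmax_mean=1.2, lmax_sd=0.3, la=0.2, lb=0.2,
                        ln_mean=0.6, theta_mean=55.0, theta_sd=8.0,
                        tropism_sigma=15.0, max_order=1),
    }
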