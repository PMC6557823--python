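import numpy as np
import pytest

import vfforecast as vf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """30 simulated eyes under default (contaminated) conditions."""
    return vf.simulate_cohort(vf.SimParams(n_eyes=30, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """40 eyes whose exams follow the true linear trends exactly
    (up to 1-dB instrument rounding)."""
    return vf.simulate_cohort(vf.noiseless_params(40, seed=5))


@pytest.fixture(scope="session")
def five_exams(small_cohort):
    return small_cohort[0].exams[:5]
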