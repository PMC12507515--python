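import numpy as np
import pytest

from cas12akin import cis_kinetics as ck
from cas12akin import synthetic_data as sd


@pytest.fixture(scope="session")
def log_time_grid():
    """16-point grid (t=0 plus 15 log-spaced points) used for fitting tests."""
    return tuple([0.0] + list(np.geomspace(2.0, 600.0, 15)))


@pytest.fixture(scope="session")
def true_params():
    return ck.CleavageParams(ka=0.2, kb=0.02, kini=0.005, kini2=0.01)


@pytest.fixture(scope="session")
def noiseless_fit(true_params, log_time_grid):
    """One noiseless synthetic replicate and its fit, shared across tests."""
    spec = sd.SynthSpec(seed=3, time_grid=log_time_grid, n_replicates=1, noise_sd=0.0)
    tc = sd.gen_timecourse(true_params, ck.InitialState(100.0), spec)[0]
    return tc, ck.fit_replicate(tc)
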