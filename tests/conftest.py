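import numpy as np
import pytest

from nmssnet import default_config, simulate, small_config
from nmssnet.network import EstimatorSettings


@pytest.fixture(scope="session")
def nmss_pair():
    """Paired baseline/follow-up NMSS-like data at the study's cohort size."""
    return simulate(default_config(11, n_subjects=499))


@pytest.fixture(scope="session")
def small_pair():
    """Paired data from the reduced 8-item generator (fast tests)."""
    return simulate(small_config(11, n_subjects=400))


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced-path estimator settings for bootstrap-heavy tests."""
    return EstimatorSettings(
        n_lambda=10, lambda_min_ratio=0.05, solver_tol=1e-3, solver_max_iter=100
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20230214)
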