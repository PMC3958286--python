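import pytest
from hypothesis import HealthCheck, settings

import mediamp as ma

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1() -> ma.ModelParameters:
    """Reference (aerobic) parameter set."""
    return ma.default_parameters()


@pytest.fixture(scope="session")
def reference_run(table1):
    """Full-resolution steady-state run at the reference conditions.

    50 intervals per layer and dt = 0.01 s (steady-state quantities are
    fixed points of the implicit scheme and insensitive to dt; checked
    against dt = 0.02 and 0.005 during development).  Shared by every
    test that reads the steady profile.
    """
    opts = ma.SolverOptions(points_per_layer=50, dt=0.01)
    tr = ma.simulate(table1, opts)
    grid = ma.build_grid(table1, opts)
    return tr, grid, opts


@pytest.fixture(scope="session")
def coarse_opts() -> ma.SolverOptions:
    """Cheap solver settings for sweep-style tests.

    The paired-run protocol cancels discretization error between the
    aerobic and anaerobic branches, so sensitivity trends survive this
    resolution (B_O2 itself moves < 1% between 10 and 50 points/layer).
    """
    return ma.SolverOptions(points_per_layer=10, dt=0.05)
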