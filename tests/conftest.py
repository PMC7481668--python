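"""Shared fixtures: converged site solutions are session-scoped because a
full forward solve takes about a second and many tests inspect the same
stations."""

import logging
import warnings

import pytest

from sedrtm import site_config, solve_steady_state

logging.getLogger("sedrtm").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def b13_solution():
    return solve_steady_state(site_config("B13"))


@pytest.fixture(scope="session")
def b15_solution():
    return solve_steady_state(site_config("B15"))


@pytest.fixture(scope="session")
def b16_solution():
    return solve_steady_state(site_config("B16"))


@pytest.fixture(scope="session")
def b17_solution():
    return solve_steady_state(site_config("B17"))


@pytest.fixture(scope="session")
def reduced_solver_opts():
    """Coarser discretization used where many forward solves are needed."""
    return dict(n_nodes=100, n_fractions=60)
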