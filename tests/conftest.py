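"""Shared fixtures: toy geometries, inflows, and cheap calibration problems."""

import numpy as np
import pytest

from pulsecal.hemodynamics import FluidConstants, SolverGrid
from pulsecal.synthetic import synthetic_inflow, toy_network


@pytest.fixture(scope="session")
def const():
    return FluidConstants()


@pytest.fixture(scope="session")
def inflow():
    return synthetic_inflow()


@pytest.fixture(scope="session")
def single_network():
    return toy_network("single")


@pytest.fixture(scope="session")
def bifurcation_network():
    return toy_network("bifurcation3")


@pytest.fixture(scope="session")
def coarse_grid():
    return SolverGrid(n_cycles=4)


@pytest.fixture(scope="session")
def surrogate_problem():
    """Fast closed-form calibration problem shared across pipeline tests."""
    from pulsecal.pipeline import make_surrogate0d_problem

    problem, truth = make_surrogate0d_problem(seed=3)
    return problem, truth


@pytest.fixture(scope="session")
def surrogate_inference(surrogate_problem):
    """One small end-to-end run on the closed-form problem (shared)."""
    from pulsecal.pipeline import PhaseConfig, run_inference

    problem, truth = surrogate_problem
    cfg = PhaseConfig.reduced(
        n_design=100, n_explore=100, emulator_budget=100,
        n_chains=4, n_burn=150, n_sample=300, bo_n_configs=10,
    )
    res = run_inference(problem, cfg, seed=7, sampler="ahmc")
    return res, truth
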