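"""Shared fixtures: small spaces, a toy rank-1 circuit, simulated trials.

Expensive artifacts (simulated trial sets, full-scale recovery runs) are
session-scoped so the acceptance tests and the unit tests share them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from divnorm.examples import example1_scaled_model, random_stimuli, simulate_trials
from divnorm.measurement import build_temporal_system
from divnorm.simulate import TemporalDNP
from divnorm.spaces import Kernel1, make_space, project1
from divnorm.volterra import VolterraProcessor, make_lowrank_kernel2

warnings.filterwarnings("ignore", message="M = .* trials is below")


def unit_kernel1(space, seed):
    c = random_stimuli(space, 1, sigma=1.0, seed=seed)[0].coeffs
    return Kernel1(space, c / np.linalg.norm(c))


def toy_dnp(L=3):
    """Small temporal DNP with rank-1 second-order kernels and mild gains."""
    s = make_space(L, 30 * np.pi)
    h21 = make_lowrank_kernel2([0.8], [unit_kernel1(s, 11)])
    h22 = make_lowrank_kernel2([0.3], [unit_kernel1(s, 12)])
    h23 = make_lowrank_kernel2([0.2], [unit_kernel1(s, 13)])
    h11 = Kernel1(s, 1.5 * unit_kernel1(s, 14).coeffs)
    h12 = Kernel1(s, 0.3 * unit_kernel1(s, 15).coeffs)
    h13 = Kernel1(s, 0.2 * unit_kernel1(s, 16).coeffs)
    return TemporalDNP(
        VolterraProcessor(0.1, h11, h21, s),
        VolterraProcessor(0.5, h12, h22, s),
        VolterraProcessor(0.5, h13, h23, s),
        s,
        s,
    )


@pytest.fixture(scope="session")
def space5():
    return make_space(5, 100 * np.pi)


@pytest.fixture(scope="session")
def toy():
    return toy_dnp()


@pytest.fixture(scope="session")
def toy_trials(toy):
    stim = random_stimuli(toy.space_in, 20, sigma=0.3, seed=42)
    return simulate_trials(toy, stim, T=7, grid=896)


@pytest.fixture(scope="session")
def toy_system(toy_trials):
    return build_temporal_system(toy_trials)


@pytest.fixture(scope="session")
def scaled_recovery():
    """Recovery run of the reduced-order temporal benchmark scenario."""
    from divnorm.scenarios import get_scenario, run_scenario

    return run_scenario(get_scenario("example1_scaled"))


@pytest.fixture(scope="session")
def example3_recovery():
    """Full spatio-temporal benchmark recovery (the slow session fixture)."""
    from divnorm.scenarios import get_scenario, run_scenario

    return run_scenario(get_scenario("example3_full"))
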