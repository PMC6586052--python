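"""Shared fixtures: reduced-scale Monte Carlo runs reused across tests.

The simulation fixtures run once per session at reduced problem sizes
(smaller boxes, fewer walkers/steps/seeds than the full-scale study
profile) and are shared by the metric, signal and acceptance tests.
"""

import warnings

import numpy as np
import pytest

from corddiff.dynamics import run_dynamics, seed_walkers
from corddiff.metrics import compute_metrics
from corddiff.study import run_compartment_study
from corddiff.substrate import Substrate


@pytest.fixture(scope="session")
def single_cylinder_series():
    """≥10⁴ walkers confined to one cylinder (r = 2.66 μm, D₀ = 2) for 75 ms."""
    sub = Substrate(
        L=50.0, g=1.0, centers=np.array([[25.0, 25.0]]), r_out=np.array([2.66]),
        d_in0=2.0,
    )
    ens = seed_walkers(sub, 12000, 0, np.random.default_rng(42))
    series = run_dynamics(
        sub, ens, duration=75.0, n_steps=10000, sample_times=[25, 50, 75], seed=42
    )
    return series[0]


@pytest.fixture(scope="session")
def large_axon_intra_study():
    """Seed-replicated intra-axonal study on the large-axon, high-density
    substrate (the acceptance-scale profile: ≥10⁴ walkers in total)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_compartment_study(
            "large_axons", "high", n_seeds=5, n_intra=2200, n_extra=0,
            n_steps=10000, duration=75.0, sample_times=[25.0, 30.0, 52.0, 75.0],
            L=200.0, d_in0=2.0, base_seed=1,
        )


def _full_study(preset, L):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_compartment_study(
            preset, "high", n_seeds=3, n_intra=1500, n_extra=1500,
            n_steps=20000, duration=75.0,
            sample_times=[5, 10, 15, 20, 25, 35, 45, 55, 65, 75],
            L=L, d_in0=2.0, d_ex0=1.0, base_seed=3,
        )


@pytest.fixture(scope="session")
def small_axon_study():
    """Both compartments, small-axon high-density substrate, reduced box."""
    return _full_study("small_axons", 50.0)


@pytest.fixture(scope="session")
def large_axon_study():
    """Both compartments, large-axon high-density substrate, reduced box."""
    return _full_study("large_axons", 100.0)


@pytest.fixture(scope="session")
def free_diffusion_series():
    """Unrestricted 2-D walk (no cylinders), D₀ = 2 μm² ms⁻¹, 10⁴ walkers."""
    sub = Substrate(
        L=50.0, g=0.75, centers=np.empty((0, 2)), r_out=np.empty(0), d_ex0=2.0
    )
    ens = seed_walkers(sub, 0, 10000, np.random.default_rng(7))
    return run_dynamics(
        sub, ens, duration=50.0, n_steps=5000, sample_times=[1, 10, 25, 50], seed=7
    )[0]


@pytest.fixture(scope="session")
def single_cylinder_metrics(single_cylinder_series):
    return compute_metrics([single_cylinder_series])
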