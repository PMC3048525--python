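"""Shared fixtures: scaled-down simulation settings and cached sweeps.

Simulation-backed tests use shortened horizons and small replicate counts;
the horizons stay several protein lifetimes (1/gamma = 500 s) long so that
endpoint distributions are at equilibrium.
"""

from dataclasses import replace

import pytest

from galevo.config import load_config
from galevo.experiments import build_feature_table
from galevo.simulate import SimulationParams


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return load_config(None)


@pytest.fixture(scope="session")
def fast_params(default_params) -> SimulationParams:
    """Short-horizon parameters for qualitative simulation checks."""
    return replace(default_params, t_end=2500.0, seed=1234)


@pytest.fixture(scope="session")
def feature_table(default_params):
    """Scaled-down 33-network feature sweep shared across scoring tests.

    10 replicates per condition at a 4000 s horizon (endpoints are at
    equilibrium well before; see docs/methods.md on problem sizes).
    """
    params = replace(default_params, t_end=4000.0, seed=20240)
    return build_feature_table(params, n_replicates=10)
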