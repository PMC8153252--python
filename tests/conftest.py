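"""Shared fixtures: synthetic sessions and cached neuron calibrations."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from gocpop.behavior import generate_behavior
from gocpop.neuron import NeuronParams, calibrate_population
from gocpop.synthetic import SyntheticSessionSpec, generate_population_activity


@lru_cache(maxsize=8)
def cached_calibration(seed: int, n_cells: int = 115):
    """Calibrated parameter sets reused across tests (deterministic)."""
    return calibrate_population(n_cells, seed=seed)


@pytest.fixture(scope="session")
def behavior300():
    return generate_behavior(300.0, seed=7)


@pytest.fixture(scope="session")
def synthetic_session(behavior300):
    """Default surrogate session: PM1 (70%) + 5 differential modes (20%)
    + noise (10%), 40 neurons, 300 s."""
    spec = SyntheticSessionSpec(seed=7)
    activity, truth = generate_population_activity(spec, behavior300)
    return spec, activity, truth


@pytest.fixture(scope="session")
def quiet_behavior():
    from gocpop.behavior import EpochParams
    return generate_behavior(60.0, seed=3,
                             epoch_params=EpochParams(active_prob=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
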