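"""Shared fixtures: synthetic models and one scaled single-NCP production run.

The production run mirrors the study conditions of a single NCP
neutralized by trivalent counterions in a 40 nm cell (Langevin dynamics,
dt = 0.01, gamma = 0.01, kT = 1) at a desk-scale step count; several
observable tests share it to keep the suite inside a sensible runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from nucleocg.forcefield import ForceFieldParams, ForceTables
from nucleocg.ncp_builder import make_synthetic_ncp
from nucleocg.simulator import (
    SimulationParams,
    initial_state,
    minimize,
    place_counterions,
    run,
)

PRODUCTION_SEED = 2013


@pytest.fixture(scope="session")
def synthetic_model():
    return make_synthetic_ncp(seed=7)


@pytest.fixture(scope="session")
def ff_params():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def production_run(ff_params):
    """(ionized model, reference model, full trajectory, sim params).

    Single NCP + 50 CoHex^3+ counterions, 5e4 steps (the full protocol used
    1e8; step count chosen for desk-scale runtime), frames every 200 steps.
    """
    model = make_synthetic_ncp(seed=PRODUCTION_SEED)
    sp = SimulationParams(
        n_steps=50_000, traj_stride=200, seed=PRODUCTION_SEED + 1
    )
    ionized = place_counterions(
        model, "CoHex", sp.box_edge, seed=PRODUCTION_SEED + 2
    )
    tables = ForceTables(ionized, ff_params)
    state = initial_state(ionized, sp)
    minimize(state, tables, sp, n_steps=200)
    traj = run(state, ionized, ff_params, sp, tables=tables)
    return ionized, model, traj, sp


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
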