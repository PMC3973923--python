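"""Shared fixtures.

The calibrated experiment is expensive (several seconds of simulated
closed-loop time), so it is built once per session and shared by the
estimation, comparison and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from firingclamp import (
    FiringClampExperiment,
    MeanderConfig,
    NeuronParams,
    ReversalSpec,
)
from firingclamp.neuron import init_steady_state


@pytest.fixture(scope="session")
def params() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def meander() -> MeanderConfig:
    return MeanderConfig()


@pytest.fixture(scope="session")
def rest_state(params):
    return init_steady_state(params)


@pytest.fixture(scope="session")
def rev(params) -> ReversalSpec:
    return ReversalSpec(V_E_mV=0.0, V_I_mV=-74.0, V_0_mV=params.V_rest_mV)


@pytest.fixture(scope="session")
def experiment() -> FiringClampExperiment:
    """A calibrated simulated firing-clamp experiment."""
    exp = FiringClampExperiment()
    exp.calibrate()
    return exp


@pytest.fixture(scope="session")
def quiescent_run(params, meander, rest_state):
    """1 s quiescent firing-clamp run at the default 0.03 ms step."""
    from firingclamp.protocol import run_firing_clamp

    return run_firing_clamp(
        params, meander, None, 1000.0, 0.03, initial_state=rest_state
    )
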