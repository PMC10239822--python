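"""Shared fixtures.

The expensive simulations (rest states, the 50 pA / 5 s step with its 60 s
AHP tail in all three variants) are session-scoped so the metric tests and
the acceptance suite reuse a single run each.
"""

from __future__ import annotations

import pytest

from pumpneuron.dynamics_engine import ModelSpec, SolverOptions, find_rest
from pumpneuron.experiments import run_step_response

VARIANTS = ("ConCon", "DynCon", "DynDyn")


@pytest.fixture(scope="session")
def rest_states():
    """Converged resting states of the three default-parameter variants."""
    out = {}
    for name in VARIANTS:
        rr = find_rest(ModelSpec.variant(name))
        assert rr.converged, rr.message
        out[name] = rr
    return out


@pytest.fixture(scope="session")
def step50(rest_states):
    """50 pA / 5 s step responses with 60 s tails, per variant.

    Maps variant -> (StepResponseMetrics, SimulationTrace); stimulus onset
    1000 ms, offset 6000 ms.
    """
    out = {}
    for name in VARIANTS:
        metrics, trace = run_step_response(
            ModelSpec.variant(name), 50.0, duration=5000.0, tail=60_000.0,
            rest=rest_states[name].state,
        )
        out[name] = (metrics, trace)
    return out


@pytest.fixture(scope="session")
def dyndyn_step50_trace(step50):
    return step50["DynDyn"][1]
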